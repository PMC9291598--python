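"""Observed-data structures for interval-censored competing risks with
missing event types, plus delimited-text I/O and validation.

Each subject carries a censoring interval and indicators:

* ``v`` -- last examination time before the event (0 if left-censored),
* ``u`` -- first examination time after the event (``inf`` if
  right-censored),
* ``delta`` = ``delta1`` + ``delta2`` -- overall event indicator split
  into interval-censoring (``delta1``) and left-censoring (``delta2``),
* ``cause`` -- event type in ``1..k`` (0 denotes right-censored,
  ``MISSING_CAUSE`` an unobserved type),
* ``r`` -- response indicator: 1 if the event type was observed.
  Right-censored subjects always have ``r = 1``.
* ``z`` -- covariates of interest, ``a`` -- auxiliary covariates that
  may predict missingness but are not of scientific interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_CAUSE",
    "ICRecord",
    "ICDataset",
    "read_dataset",
    "write_dataset",
    "validate",
]

#: internal integer code for an unobserved event type
MISSING_CAUSE = -1


@dataclass(frozen=True)
class ICRecord:
    """One subject's observed data."""

    id: object
    v: float
    u: float
    delta: int
    delta1: int
    delta2: int
    cause: int  # 1..k, 0 = right-censored, MISSING_CAUSE = unobserved
    r: int
    z: np.ndarray
    a: np.ndarray


@dataclass
class ICDataset:
    """Column-oriented sample of :class:`ICRecord` s.

    Arrays are aligned by subject; ``z`` is ``(n, d)`` and ``a`` is
    ``(n, n_aux)`` (possibly zero columns).
    """

    ids: np.ndarray
    v: np.ndarray
    u: np.ndarray
    cause: np.ndarray
    r: np.ndarray
    z: np.ndarray
    a: np.ndarray
    k: int = 2
    z_names: Sequence[str] = field(default=None)
    a_names: Sequence[str] = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.v)
        self.ids = np.asarray(self.ids)
        self.v = np.asarray(self.v, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.cause = np.asarray(self.cause, dtype=int)
        self.r = np.asarray(self.r, dtype=int)
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.shape[0] != n:
            self.z = self.z.T
        self.a = np.asarray(self.a, dtype=float)
        if self.a.size == 0:
            self.a = np.zeros((n, 0))
        else:
            self.a = np.atleast_2d(self.a)
            if self.a.shape[0] != n:
                self.a = self.a.T
        if self.z_names is None:
            self.z_names = [f"z{j+1}" for j in range(self.z.shape[1])]
        if self.a_names is None:
            self.a_names = [f"a{j+1}" for j in range(self.a.shape[1])]
        if self.k < 2:
            raise ValueError("at least two competing event types are required")

    # --- derived indicators -------------------------------------------------
    @property
    def delta(self) -> np.ndarray:
        return (np.isfinite(self.u)).astype(int)

    @property
    def delta1(self) -> np.ndarray:
        return ((self.v > 0) & np.isfinite(self.u)).astype(int)

    @property
    def delta2(self) -> np.ndarray:
        return ((self.v == 0) & np.isfinite(self.u)).astype(int)

    @property
    def n(self) -> int:
        return len(self.v)

    @property
    def d(self) -> int:
        return self.z.shape[1]

    @property
    def n_aux(self) -> int:
        return self.a.shape[1]

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[ICRecord]:
        d, d1, d2 = self.delta, self.delta1, self.delta2
        for i in range(self.n):
            yield ICRecord(
                id=self.ids[i], v=float(self.v[i]), u=float(self.u[i]),
                delta=int(d[i]), delta1=int(d1[i]), delta2=int(d2[i]),
                cause=int(self.cause[i]), r=int(self.r[i]),
                z=self.z[i], a=self.a[i],
            )

    def subset(self, idx) -> "ICDataset":
        """Row-subset (bootstrap resampling, complete-case filtering)."""
        idx = np.asarray(idx)
        return ICDataset(
            ids=self.ids[idx], v=self.v[idx], u=self.u[idx],
            cause=self.cause[idx], r=self.r[idx],
            z=self.z[idx], a=self.a[idx], k=self.k,
            z_names=self.z_names, a_names=self.a_names,
        )

    def observation_times(self) -> np.ndarray:
        """Pooled {V_i, U_i} used for sieve knot placement."""
        return np.concatenate([self.v, self.u])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "v": self.v, "u": self.u})
        cause = self.cause.astype(object)
        cause[self.cause == MISSING_CAUSE] = np.nan
        df["cause"] = cause
        for j, name in enumerate(self.z_names):
            df[name] = self.z[:, j]
        for j, name in enumerate(self.a_names):
            df[name] = self.a[:, j]
        return df


def _derive_from_columns(v, u, cause, missing_code) -> tuple[np.ndarray, np.ndarray]:
    """Derive (cause codes, r) from raw columns; u may be NaN for
    right-censored, cause equal to ``missing_code`` flags missingness."""
    n = len(v)
    out_cause = np.zeros(n, dtype=int)
    r = np.ones(n, dtype=int)
    for i in range(n):
        ci = cause[i]
        is_missing = (
            (ci is None)
            or (isinstance(ci, float) and np.isnan(ci))
            or (missing_code is not None and ci == missing_code)
            or (isinstance(ci, str) and ci.strip() == "")
        )
        if is_missing:
            out_cause[i] = MISSING_CAUSE
            r[i] = 0
        else:
            out_cause[i] = int(ci)
    return out_cause, r


def read_dataset(
    path,
    k: int = 2,
    missing_code=None,
    id_col: str = "id",
    v_col: str = "v",
    u_col: str = "u",
    cause_col: str = "cause",
    z_cols: Sequence[str] | None = None,
    a_cols: Sequence[str] | None = None,
    sep: str = ",",
) -> ICDataset:
    """Read a delimited-text dataset and derive all indicators.

    Right censoring is encoded as cause 0 with ``u`` empty or the literal
    ``Inf`` (both accepted).  A cause equal to ``missing_code`` (default:
    empty field) marks an unobserved event type.  Raises ``ValueError``
    naming the first offending row for impossible records.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, v_col, u_col, cause_col):
        if col not in df.columns:
            raise ValueError(f"required column '{col}' not found in {path}")
    if z_cols is None:
        z_cols = [c for c in df.columns if c.startswith("z")]
    if a_cols is None:
        a_cols = [c for c in df.columns if c.startswith("a")]
    v = df[v_col].to_numpy(dtype=float)
    u = df[u_col].to_numpy(dtype=float)  # empty fields -> NaN
    u = np.where(np.isnan(u), np.inf, u)
    cause, r = _derive_from_columns(v, u, df[cause_col].tolist(), missing_code)
    # right censoring: cause 0 or infinite u
    right = (cause == 0) | ~np.isfinite(u)
    if np.any(right & (cause == MISSING_CAUSE)):
        i = int(np.argmax(right & (cause == MISSING_CAUSE)))
        raise ValueError(
            f"row {i}: right-censored record with missing cause code "
            "(right-censoring status is always observed)"
        )
    u = np.where(right, np.inf, u)
    cause = np.where(right, 0, cause)
    if np.any(v < 0):
        raise ValueError(f"row {int(np.argmax(v < 0))}: negative time")
    ev = np.isfinite(u)
    if np.any(ev & (v >= u)):
        raise ValueError(f"row {int(np.argmax(ev & (v >= u)))}: event record with v >= u")
    if np.any(ev & (cause > k)):
        raise ValueError(f"row {int(np.argmax(ev & (cause > k)))}: cause exceeds k={k}")
    ds = ICDataset(
        ids=df[id_col].to_numpy(), v=v, u=u, cause=cause, r=r,
        z=df[list(z_cols)].to_numpy(dtype=float),
        a=df[list(a_cols)].to_numpy(dtype=float) if a_cols else np.zeros((len(v), 0)),
        k=k, z_names=list(z_cols), a_names=list(a_cols),
    )
    return ds


def write_dataset(ds: ICDataset, path, sep: str = ",") -> None:
    """Write the CSV dialect read back by :func:`read_dataset`:
    right censoring as cause 0 / ``u = Inf``, missing cause as an empty
    field."""
    df = ds.to_frame()
    df.to_csv(path, sep=sep, index=False)


def validate(ds: ICDataset) -> dict:
    """Check every record invariant; returns per-rule violation counts.

    Zero violations are required before fitting.
    """
    delta, d1, d2 = ds.delta, ds.delta1, ds.delta2
    ev = delta == 1
    report = {
        "delta_split (delta = delta1 + delta2)": int(np.sum(delta != d1 + d2)),
        "left-censoring implies v = 0": int(np.sum((d2 == 1) & (ds.v != 0))),
        "right-censored implies r = 1": int(np.sum((delta == 0) & (ds.r != 1))),
        "event implies v < u < inf": int(
            np.sum(ev & ((ds.v >= ds.u) | ~np.isfinite(ds.u)))
        ),
        "observed event implies cause in 1..k": int(
            np.sum(ev & (ds.r == 1) & ((ds.cause < 1) | (ds.cause > ds.k)))
        ),
        "r = 0 implies cause missing": int(
            np.sum((ds.r == 0) & (ds.cause != MISSING_CAUSE))
        ),
        "nonnegative times": int(np.sum(ds.v < 0)),
    }
    report["total"] = sum(report.values())
    return report
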
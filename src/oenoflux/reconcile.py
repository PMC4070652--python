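"""Elemental-balance data reconciliation and gross-error detection.

Measured exchange rates r_m never close the element balances exactly.  With a
constraint matrix whose rows are conservation relations expressible in the
measured rates alone (the redundancy matrix R), the classical treatment is:

* residual        epsilon = R r_m
* reconciled      r_hat = r_m - F R' (R F R')^+ epsilon   (F = covariance)
* consistency     h = epsilon' (R F R')^+ epsilon

Under correctly specified Gaussian noise, h is chi-square distributed with
rank(R) degrees of freedom, so h above the 95% quantile (7.81 at redundancy
3, 9.49 at 4) flags a gross measurement error, which serial elimination then
localises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MeasurementSet",
    "ReconciliationResult",
    "redundancy_matrix",
    "reconcile",
    "chi2_critical",
    "localize_gross_error",
]

#: singular values below this fraction of the largest are treated as zero
PINV_RTOL = 1e-10


@dataclass
class MeasurementSet:
    """Measured specific rates (signed, mmol/gDCW/h; growth in h^-1) over
    named exchange quantities, with their covariance.

    ``F`` defaults to diag(sd^2); measurements lacking an sd get a floor of
    ``cv_floor`` times |rate| so that no hard (zero-variance) value blocks
    the reconciliation.
    """

    names: list[str]
    r_m: np.ndarray
    sd: np.ndarray | None = None
    F: np.ndarray | None = None
    condition_label: str = ""
    cv_floor: float = 0.05

    def __post_init__(self):
        self.r_m = np.asarray(self.r_m, dtype=float)
        if len(self.names) != self.r_m.size:
            raise ValueError("names and r_m dimensions differ")
        if self.F is None:
            if self.sd is None:
                raise ValueError("supply either sd or a full covariance F")
            sd = np.asarray(self.sd, dtype=float).copy()
            if sd.size != self.r_m.size:
                raise ValueError("sd and r_m dimensions differ")
            floor = self.cv_floor * np.abs(self.r_m)
            sd = np.where(sd > 0, sd, floor)
            if np.any(sd <= 0):
                bad = [self.names[i] for i in np.flatnonzero(sd <= 0)]
                raise ValueError(f"zero variance and zero rate for {bad}; set an sd")
            self.sd = sd
            self.F = np.diag(sd**2)
        else:
            self.F = np.asarray(self.F, dtype=float)
            if self.F.shape != (self.r_m.size, self.r_m.size):
                raise ValueError("F shape does not match r_m")
            if not np.allclose(self.F, self.F.T, atol=1e-12):
                raise ValueError("F must be symmetric")
            eigs = np.linalg.eigvalsh(self.F)
            if eigs.min() < -1e-10 * max(1.0, eigs.max()):
                raise ValueError("F must be positive semi-definite")

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ReconciliationResult:
    r_hat: np.ndarray
    epsilon: np.ndarray
    h: float
    redundancy: int
    p_value: float
    verdict: str  # "consistent" | "gross_error"
    critical_value: float
    significance: float
    names: list[str] = field(default_factory=list)
    eliminated: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return self.verdict == "consistent"


def redundancy_matrix(
    E: np.ndarray,
    measured: Sequence[int],
    unmeasured: Sequence[int] = (),
) -> np.ndarray:
    """Project the constraint matrix onto the measured rates: with E split
    into measured columns E_m and unmeasured columns E_c,

        R = E_m - E_c pinv(E_c) E_m

    annihilates every constraint direction that an unmeasured rate can
    absorb; rank(R) is the redundancy of the measurement set."""
    E = np.asarray(E, dtype=float)
    E_m = E[:, list(measured)]
    if len(unmeasured) == 0:
        return E_m.copy()
    E_c = E[:, list(unmeasured)]
    return E_m - E_c @ np.linalg.pinv(E_c, rcond=PINV_RTOL) @ E_m


def _matrix_rank(A: np.ndarray) -> int:
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    return int(np.sum(s > PINV_RTOL * s[0])) if s.size and s[0] > 0 else 0


def chi2_critical(df: int, level: float) -> float:
    """Upper chi-square quantile used as the consistency-test threshold
    (7.81 at df=3, 9.49 at df=4 for the customary 95% level)."""
    if df < 1 or int(df) != df:
        raise ValueError("degrees of freedom must be a positive integer")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    return float(stats.chi2.ppf(level, df))


def reconcile(
    ms: MeasurementSet,
    R: np.ndarray,
    significance: float = 0.05,
) -> ReconciliationResult:
    """Covariance-weighted minimal adjustment of the measured rates onto the
    constraint space R r = 0, with the chi-square consistency test.

    The reconciled vector solves min (r - r_m)' F^-1 (r - r_m) s.t. R r = 0;
    h = 0 exactly when the measurements already satisfy the balances, and the
    verdict is "consistent" iff h stays below the upper chi-square quantile at
    ``1 - significance`` with rank(R) degrees of freedom.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    redundancy = _matrix_rank(R)
    if redundancy < 1:
        raise ValueError("constraint matrix has rank 0; nothing to reconcile")

    eps = R @ ms.r_m
    P = R @ ms.F @ R.T
    if _matrix_rank(P) < redundancy:
        # a violated constraint touching only zero-variance measurements
        violated = np.abs(eps) > 1e-10 * max(1.0, float(np.abs(ms.r_m).max()))
        if np.any(violated):
            raise ValueError(
                "R F R' is singular on a violated constraint: a zero-variance "
                "measurement participates in it and cannot be reconciled"
            )
    P_inv = np.linalg.pinv(P, rcond=PINV_RTOL)
    r_hat = ms.r_m - ms.F @ R.T @ P_inv @ eps
    h = float(eps @ P_inv @ eps)
    h = max(h, 0.0)
    level = 1.0 - significance
    crit = chi2_critical(redundancy, level)
    p_value = float(stats.chi2.sf(h, redundancy))
    verdict = "consistent" if h < crit else "gross_error"
    return ReconciliationResult(
        r_hat=r_hat,
        epsilon=eps,
        h=h,
        redundancy=redundancy,
        p_value=p_value,
        verdict=verdict,
        critical_value=crit,
        significance=significance,
        names=list(ms.names),
    )


def localize_gross_error(
    ms: MeasurementSet,
    R: np.ndarray,
    significance: float = 0.05,
) -> list[tuple[str, float]]:
    """Serial elimination: re-test the consistency index with each measurement
    in turn treated as unmeasured (its column projected out of R).  Returns
    (name, h_after_elimination) sorted ascending — the top entry is the
    suspected gross error when dropping it restores consistency.  Ties are
    broken by the larger standardised residual of the candidate."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    base = reconcile(ms, R, significance)
    if base.redundancy < 2:
        raise ValueError("gross-error localisation needs redundancy >= 2")

    # standardised adjustments for tie-breaking
    adjust = np.abs(ms.r_m - base.r_hat) / np.sqrt(np.maximum(np.diag(ms.F), 1e-300))

    results: list[tuple[str, float, float]] = []
    n = len(ms.names)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        R_i = redundancy_matrix(R, measured=keep, unmeasured=[i])
        if _matrix_rank(R_i) < 1:
            continue
        sub = MeasurementSet(
            names=[ms.names[j] for j in keep],
            r_m=ms.r_m[keep],
            F=ms.F[np.ix_(keep, keep)],
            condition_label=ms.condition_label,
        )
        res = reconcile(sub, R_i, significance)
        results.append((ms.names[i], res.h, float(adjust[i])))
    results.sort(key=lambda item: (item[1], -item[2]))
    return [(name, h) for name, h, _ in results]
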
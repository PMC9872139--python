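"""Stage 1: per-marker univariable Cox screening.

Each binary marker is fitted in its own univariable Cox proportional-hazards
model (Newton iteration on the partial likelihood, Efron correction for tied
event times) and markers with a Wald p-value below the screening threshold
are retained.  No multiple-testing correction is applied: the threshold is a
deliberately rough pre-filter, not an inferential claim.

The single-covariate fit is fully vectorised so that screening hundreds of
markers (or running large null simulations) stays cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import BinaryGenotypeMatrix, SurvivalData

logger = logging.getLogger(__name__)

__all__ = ["UniCoxResult", "ScreenResult", "univariable_cox", "screen_markers"]

_MAX_ABS_BETA = 15.0  # beyond this the likelihood is effectively monotone


@dataclass
class UniCoxResult:
    coef: float
    hr: float
    se: float
    p: float
    converged: bool
    carriers: int


@dataclass
class ScreenResult:
    """Per-marker screening table plus bookkeeping counts."""

    table: pd.DataFrame  # columns: marker, coef, hr, se, p, carriers, converged
    retained: list[str]
    n_tested: int
    n_excluded: int  # <2 carriers / constant columns, excluded pre-fit

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class _SortedSurv:
    """Survival data pre-sorted by time with tie groups resolved once."""

    def __init__(self, surv: SurvivalData):
        if surv.n_events == 0:
            raise ValueError("survival data contains no events; Cox fit undefined")
        self.order = np.argsort(surv.time, kind="stable")
        self.t = surv.time[self.order]
        self.e = surv.event[self.order].astype(bool)
        # unique event times and, per event, its group index
        self.ut = np.unique(self.t[self.e])
        self.start = np.searchsorted(self.t, self.ut, side="left")  # first risk-set index
        gi = np.searchsorted(self.ut, self.t[self.e])
        self.d = np.bincount(gi, minlength=len(self.ut)).astype(float)
        # Efron fractions l/d for l = 0..d-1, flattened over all groups
        reps = self.d.astype(int)
        offs = np.repeat(np.cumsum(reps) - reps, reps)
        self.frac = (np.arange(reps.sum()) - offs) / np.repeat(self.d, reps)
        self.grp = np.repeat(np.arange(len(self.ut)), reps)


def _suffix_sum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1])[::-1]


def _efron_loglik_U_I(x: np.ndarray, ss: _SortedSurv, beta: float):
    """Log partial likelihood, score and information for one covariate."""
    w = np.exp(beta * x)
    xw = x * w
    x2w = x * xw
    A0 = _suffix_sum(w)[ss.start]
    A1 = _suffix_sum(xw)[ss.start]
    A2 = _suffix_sum(x2w)[ss.start]
    ev = ss.e
    gi = np.searchsorted(ss.ut, ss.t[ev])
    B0 = np.bincount(gi, weights=w[ev], minlength=len(ss.ut))
    B1 = np.bincount(gi, weights=xw[ev], minlength=len(ss.ut))
    B2 = np.bincount(gi, weights=x2w[ev], minlength=len(ss.ut))
    den = A0[ss.grp] - ss.frac * B0[ss.grp]
    n1 = A1[ss.grp] - ss.frac * B1[ss.grp]
    n2 = A2[ss.grp] - ss.frac * B2[ss.grp]
    ll = beta * float(x[ev].sum()) - float(np.log(den).sum())
    U = float(x[ev].sum()) - float(np.sum(n1 / den))
    I = float(np.sum(n2 / den - (n1 / den) ** 2))
    return ll, U, I


def _fit_one(x_sorted: np.ndarray, ss: _SortedSurv, max_iter: int = 30, tol: float = 1e-9):
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, U, I = _efron_loglik_U_I(x_sorted, ss, beta)
        if I <= 1e-12:
            break
        step = U / I
        beta += np.clip(step, -2.0, 2.0)  # damped for stability on rare carriers
        if abs(beta) > _MAX_ABS_BETA:
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, I = _efron_loglik_U_I(x_sorted, ss, beta)
    se = 1.0 / np.sqrt(I) if I > 1e-12 else np.inf
    return beta, se, converged


def univariable_cox(x: np.ndarray, surv: SurvivalData) -> UniCoxResult:
    """Single-covariate Cox PH fit with Efron tie handling and Wald test.

    A constant covariate yields ``p=1`` with ``converged=False``; monotone
    likelihoods (e.g. a rare marker perfectly separating early deaths) are
    flagged as non-converged with an untrustworthy, clipped coefficient.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(surv):
        raise ValueError("x and survival data must be aligned")
    carriers = int(np.sum(x != 0))
    if np.all(x == x[0]):
        return UniCoxResult(0.0, 1.0, np.inf, 1.0, False, carriers)
    ss = _SortedSurv(surv)
    beta, se, converged = _fit_one(x[ss.order], ss)
    if np.isfinite(se) and converged:
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 1.0
    return UniCoxResult(
        coef=beta, hr=float(np.exp(beta)), se=se, p=float(p), converged=converged,
        carriers=carriers,
    )


def screen_markers(
    X: BinaryGenotypeMatrix,
    surv: SurvivalData,
    alpha: float = 0.05,
    min_carriers: int = 2,
) -> tuple[BinaryGenotypeMatrix, ScreenResult]:
    """Retain markers whose univariable Cox Wald p-value is below ``alpha``.

    Markers with fewer than ``min_carriers`` carriers (or constant columns)
    are excluded before fitting; non-converged fits are never retained.
    Column order of the retained matrix follows the input.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    ss = _SortedSurv(surv)
    rows = []
    n_excluded = 0
    for j, gene in enumerate(X.gene_ids):
        x = X.values[:, j].astype(float)
        carriers = int(x.sum())
        if carriers < min_carriers or carriers > len(x) - 1:
            n_excluded += 1
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, carriers, False, False))
            continue
        beta, se, converged = _fit_one(x[ss.order], ss)
        p = 2.0 * stats.norm.sf(abs(beta / se)) if (converged and np.isfinite(se)) else 1.0
        keep = converged and p < alpha
        rows.append((gene, beta, float(np.exp(beta)), se, p, carriers, converged, keep))
    table = pd.DataFrame(
        rows, columns=["marker", "coef", "hr", "se", "p", "carriers", "converged", "retained"]
    )
    retained_idx = np.flatnonzero(table["retained"].to_numpy())
    retained = [X.gene_ids[j] for j in retained_idx]
    logger.info(
        "screen_markers: %d/%d retained at alpha=%g (%d excluded pre-fit)",
        len(retained), X.shape[1], alpha, n_excluded,
    )
    if not retained:
        logger.warning("screen_markers: no markers retained — downstream will see no signal")
    X_red = X.select_columns(retained_idx) if len(retained_idx) else BinaryGenotypeMatrix(
        values=np.zeros((X.shape[0], 0), dtype=np.int8),
        sample_ids=list(X.sample_ids),
        gene_ids=[],
    )
    return X_red, ScreenResult(
        table=table, retained=retained, n_tested=X.shape[1] - n_excluded, n_excluded=n_excluded
    )
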
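"""End-to-end taxon calibration, group prediction, and between-group tests.

Ties the chain together: a calibration set is preprocessed, cross-validated,
fitted at the AIC-chosen factor count and permutation-validated
(:func:`build_taxon_model`); archaeological replicate spectra are predicted
and summarised per taxon x stratigraphic-unit group; group means are compared
with a one-way ANOVA and Tukey-Kramer pairwise tests, summarised as a compact
letter display (groups sharing a letter do not differ at the chosen alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, SpuriousModelError, ValidationError
from .pls import CVResult, PLSModel, TemperaturePLS
from .rounding import round_half_away
from .spectra import CalibrationSet, SpectralMatrix
from .validation import PermutationResult, accept_model, permutation_null

__all__ = [
    "TaxonCalibration",
    "TemperaturePrediction",
    "GroupComparison",
    "build_taxon_model",
    "predict_group",
    "one_way_anova",
    "tukey_hsd",
    "su_contrast",
]

log = logging.getLogger("charterm")


@dataclass
class TaxonCalibration:
    """A fitted, cross-validated and permutation-checked taxon model."""

    taxon: str
    model: PLSModel
    cv: CVResult
    perm: PermutationResult
    accepted: bool
    reason: str
    estimator: TemperaturePLS | None = None


@dataclass
class TemperaturePrediction:
    """Per-replicate predictions for one taxon x stratigraphic-unit group."""

    group: str
    per_spectrum: np.ndarray
    taxon: str = "custom"

    def __post_init__(self) -> None:
        self.per_spectrum = np.asarray(self.per_spectrum, dtype=float)
        if self.per_spectrum.size == 0:
            raise ValidationError("a prediction group needs at least one spectrum")

    @property
    def mean(self) -> float:
        return float(self.per_spectrum.mean())

    @property
    def min(self) -> float:
        return float(self.per_spectrum.min())

    @property
    def max(self) -> float:
        return float(self.per_spectrum.max())

    def summary(self, ndigits: int = 0) -> dict:
        return {
            "group": self.group,
            "n": int(self.per_spectrum.size),
            "mean": round_half_away(self.mean, ndigits),
            "min": round_half_away(self.min, ndigits),
            "max": round_half_away(self.max, ndigits),
        }


def build_taxon_model(
    cal: CalibrationSet,
    window: int = 5,
    f_max: int = 4,
    use_snv: bool = True,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    r2_mode: str = "pearson",
) -> TaxonCalibration:
    """Calibrate one taxon: CV + AIC factor choice, final fit, permutation check."""
    y = cal.temperatures
    if len(np.unique(y)) < 3:
        raise ValidationError("need at least 3 distinct calibration temperatures")
    est = TemperaturePLS(
        n_factors="aic", f_max=f_max, window=window, snv=use_snv, r2_mode=r2_mode
    ).fit(cal.matrix, y)
    est.model_.taxon = cal.taxon
    perm = permutation_null(
        cal.matrix, y, f_max=f_max, n_perm=n_perm, seed=seed, window=window,
        use_snv=use_snv, r2_mode=r2_mode,
    )
    ok, reason = accept_model(perm, alpha)
    log.info("calibration %s: %s", cal.taxon, reason)
    return TaxonCalibration(cal.taxon, est.model_, est.cv_, perm, ok, reason, est)


def predict_group(
    tc: TaxonCalibration,
    spectra: SpectralMatrix,
    group: str,
    force: bool = False,
) -> TemperaturePrediction:
    """Predict every replicate spectrum of a group with a taxon's model.

    Predictions are not clipped to the 350-600 degC calibration range;
    extrapolation is logged.  A model flagged spurious refuses unless forced.
    """
    if not tc.accepted and not force:
        raise SpuriousModelError(
            f"model for {tc.taxon} failed permutation validation ({tc.reason})"
        )
    from .pls import predict as _predict

    vals = _predict(tc.model, spectra)
    if vals.min() < 350 or vals.max() > 600:
        log.warning(
            "group %s: predictions extrapolate beyond the 350-600 degC calibration range",
            group,
        )
    return TemperaturePrediction(group, vals, taxon=tc.taxon)


def _check_groups(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs at least 2 values")
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if ssw <= 0:
        raise DegenerateDataError("zero within-group variance")
    return groups, ssw


def one_way_anova(groups):
    """Classical one-way ANOVA decomposition.

    Returns (F, df_between, df_within, p).  SST = SSB + SSW by construction.
    """
    groups, ssw = _check_groups(groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


@dataclass
class GroupComparison:
    """ANOVA + Tukey-Kramer pairwise results with a compact letter display."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey_pairs: list = field(default_factory=list)  # (i, j, diff, adjusted p)
    letters: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    alpha: float = 0.05


def _compact_letters(k: int, means, nonsig: set[tuple[int, int]]) -> list[str]:
    """Letters from maximal cliques of the non-significance graph.

    Exact for the small group counts used here: two groups share a letter if
    and only if their pairwise adjusted p exceeds alpha.  Letter order follows
    decreasing group mean of the clique's top member.
    """
    adj = [[i == j or (min(i, j), max(i, j)) in nonsig for j in range(k)] for i in range(k)]
    cliques = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if all(adj[i][j] for i, j in combinations(members, 2)):
            cliques.append(set(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    maximal.sort(key=lambda c: -max(means[i] for i in c))
    letters = ["" for _ in range(k)]
    for li, c in enumerate(maximal):
        ch = chr(ord("a") + li)
        for i in c:
            letters[i] += ch
    return letters


def tukey_hsd(groups, alpha: float = 0.05, labels=None) -> GroupComparison:
    """Tukey-Kramer all-pairs comparison via the studentized-range distribution.

    Handles unequal group sizes; adjusted p for pair (i, j) is the survival
    function of the studentized range at q = |mi - mj| / sqrt(MSW/2 (1/ni+1/nj))
    with k groups and the ANOVA within-group df.
    """
    groups, ssw = _check_groups(groups)
    k = len(groups)
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(k)]
    f, df_b, df_w, p = one_way_anova(groups)
    msw = ssw / df_w
    means = [float(g.mean()) for g in groups]
    ns = [len(g) for g in groups]
    pairs = []
    nonsig = set()
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
        q = abs(diff) / se
        padj = float(stats.studentized_range.sf(q, k, df_w))
        pairs.append((i, j, float(diff), padj))
        if padj > alpha:
            nonsig.add((i, j))
    letters = _compact_letters(k, means, nonsig)
    return GroupComparison(f, df_b, df_w, p, pairs, letters, labels, alpha)


def su_contrast(pred_a: TemperaturePrediction, pred_b: TemperaturePrediction):
    """Difference of group mean temperatures (a - b) for one taxon across SUs.

    Returns (unrounded, rounded-to-integer) degC.
    """
    if pred_a.taxon != pred_b.taxon:
        raise ValidationError(
            f"cannot contrast different taxa ({pred_a.taxon} vs {pred_b.taxon})"
        )
    diff = pred_a.mean - pred_b.mean
    return diff, round_half_away(diff, 0)
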
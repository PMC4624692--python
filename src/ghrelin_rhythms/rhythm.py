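"""One-way ANOVA, Student-Newman-Keuls grouping, and rhythm detection.

A tissue x gene expression series is declared rhythmic by the dual
criterion used throughout this analysis: one-way ANOVA across sampling
times significant at alpha = 0.05 AND the cosinor zero-amplitude test
significant at alpha = 0.005.  The SNK post-hoc is protected: it is run
only when the omnibus ANOVA is significant, and its result is the familiar
letter display (sampling times sharing a letter are not significantly
different).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .cosinor import CosinorFit
from .design import ALPHA_ANOVA, ALPHA_COSINOR

logger = logging.getLogger(__name__)

GroupMap = dict[float, np.ndarray]


class StatsError(ValueError):
    """Invalid input to an ANOVA/SNK computation."""


@dataclass(frozen=True)
class AnovaResult:
    """Classical fixed-effects one-way ANOVA summary.

    ``degenerate`` flags zero within-group variance with unequal group
    means, in which case ``f`` is infinite and ``p`` is reported as 0.
    """

    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict[float, float]
    group_n: dict[float, int]
    degenerate: bool = False


@dataclass(frozen=True)
class SnkGrouping:
    """SNK letter display: sampling time -> letter string at level ``alpha``."""

    letters: dict[float, str]
    alpha: float


@dataclass(frozen=True)
class RhythmDecision:
    """Per tissue x gene verdict of the dual rhythm-detection criterion."""

    tissue: str
    gene: str
    anova: AnovaResult
    snk: SnkGrouping | None
    cosinor: CosinorFit
    is_rhythmic: bool
    alpha_anova: float = ALPHA_ANOVA
    alpha_cosinor: float = ALPHA_COSINOR


def _as_groups(groups: dict[float, np.ndarray]) -> GroupMap:
    out: GroupMap = {}
    for k, v in groups.items():
        arr = np.asarray(v, dtype=float).ravel()
        if arr.size < 2:
            raise StatsError(f"group {k!r} has fewer than 2 observations")
        if not np.isfinite(arr).all():
            raise StatsError(f"group {k!r} contains non-finite values")
        out[float(k)] = arr
    if len(out) < 2:
        raise StatsError("need at least 2 groups")
    return out


def one_way_anova(groups: dict[float, np.ndarray]) -> AnovaResult:
    """Fixed-effects one-way ANOVA of expression across sampling times.

    ``groups`` maps each sampling time to its per-fish values.  Groups with
    zero pooled within-group variance but unequal means are degenerate:
    ``f = inf``, ``p = 0``, flagged.
    """
    g = _as_groups(groups)
    k = len(g)
    n_total = sum(a.size for a in g.values())
    grand = sum(a.sum() for a in g.values()) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in g.values())
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in g.values())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    means = {zt: float(a.mean()) for zt, a in g.items()}
    ns = {zt: int(a.size) for zt, a in g.items()}
    # Degeneracy judged relative to the data's scale: float residue from
    # identical values must not masquerade as real variance.
    total_ss = ss_between + ss_within
    value_scale = max(1.0, sum(float(a @ a) for a in g.values()))
    if total_ss <= 1e-12 * value_scale:
        return AnovaResult(0.0, 1.0, df_between, df_within, 0.0, means, ns)
    if ss_within <= 1e-12 * total_ss:
        logger.info("ANOVA degenerate: zero within-group variance, unequal means")
        return AnovaResult(
            float("inf"), 0.0, df_between, df_within, 0.0, means, ns, degenerate=True
        )
    f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), p, df_between, df_within, float(ms_within), means, ns)


def _snk_significant(
    means: np.ndarray, ns: np.ndarray, i: int, j: int, ms_within: float, df_within: int, alpha: float
) -> bool:
    """Studentized-range test of the stretch spanning sorted positions i..j."""
    r = j - i + 1
    if ms_within <= 0.0:
        return means[j] > means[i]
    stretch_n = ns[i : j + 1]
    n_h = r / np.sum(1.0 / stretch_n)  # harmonic mean of the stretch's sizes
    q = (means[j] - means[i]) / np.sqrt(ms_within / n_h)
    return bool(q > _q_critical(alpha, r, df_within))


@lru_cache(maxsize=4096)
def _q_critical(alpha: float, r: int, df_within: int) -> float:
    """Upper-alpha studentized-range quantile q(alpha, r, df); cached because
    scipy evaluates it by slow numerical inversion."""
    return float(stats.studentized_range.ppf(1.0 - alpha, r, df_within))


def snk_posthoc(
    anova: AnovaResult, groups: dict[float, np.ndarray], alpha: float = ALPHA_ANOVA
) -> SnkGrouping:
    """Student-Newman-Keuls stepdown comparison of group means.

    Means are sorted; each stretch of ``r`` ordered means is tested against
    the studentized-range critical value ``q(alpha, r, df_within)``; a
    non-significant stretch is declared homogeneous and never subdivided
    (the classical containment rule).  Unequal group sizes enter through
    the harmonic mean of the stretch's sizes.  The homogeneous stretches
    are then swept into compact letters.
    """
    g = _as_groups(groups)
    # Sort by ascending mean; ties broken by ascending sampling time.
    order = sorted(g, key=lambda zt: (g[zt].mean(), zt))
    means = np.array([g[zt].mean() for zt in order])
    ns = np.array([g[zt].size for zt in order], dtype=float)
    k = len(order)

    homogeneous: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()

    def recurse(i: int, j: int) -> None:
        if (i, j) in seen:
            return
        seen.add((i, j))
        if i >= j:
            return
        if _snk_significant(means, ns, i, j, anova.ms_within, anova.df_within, alpha):
            recurse(i, j - 1)
            recurse(i + 1, j)
        else:
            homogeneous.add((i, j))

    recurse(0, k - 1)

    # Keep maximal homogeneous stretches; uncovered groups stand alone.
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in homogeneous)
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    for i in range(k):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()

    labels = {zt: "" for zt in order}
    for letter, (i, j) in zip(_letter_stream(), maximal):
        for pos in range(i, j + 1):
            labels[order[pos]] += letter
    letters = {zt: "".join(sorted(labels[zt])) for zt in order}
    return SnkGrouping(letters=letters, alpha=alpha)


def _letter_stream():
    for ch in string.ascii_lowercase:
        yield ch
    for ch1 in string.ascii_lowercase:  # pragma: no cover - >26 stretches
        for ch2 in string.ascii_lowercase:
            yield ch1 + ch2


def detect_rhythm(
    tissue: str,
    gene: str,
    groups: dict[float, np.ndarray],
    fit: CosinorFit,
    alpha_anova: float = ALPHA_ANOVA,
    alpha_cosinor: float = ALPHA_COSINOR,
) -> RhythmDecision:
    """Apply the dual rhythm criterion to one tissue x gene series.

    Rhythmic iff ANOVA ``p < alpha_anova`` AND the cosinor zero-amplitude
    ``p < alpha_cosinor``.  The SNK letter display is computed only when
    the omnibus ANOVA is significant (protected post-hoc); otherwise all
    groups share a single letter.
    """
    anova = one_way_anova(groups)
    if anova.p < alpha_anova:
        snk = snk_posthoc(anova, groups, alpha=alpha_anova)
    else:
        snk = None
        logger.info("ANOVA p=%.3g >= %g for (%s, %s): SNK not run", anova.p, alpha_anova, tissue, gene)
    is_rhythmic = (anova.p < alpha_anova) and (fit.p_zero_amplitude < alpha_cosinor)
    return RhythmDecision(
        tissue=tissue,
        gene=gene,
        anova=anova,
        snk=snk,
        cosinor=fit,
        is_rhythmic=bool(is_rhythmic),
        alpha_anova=alpha_anova,
        alpha_cosinor=alpha_cosinor,
    )
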
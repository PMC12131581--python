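"""Nonparametric comparison battery for unit-level transition statistics.

Group comparisons operate on player-side units (one player's matrix
within one match): Mann-Whitney U for two-level factors (gender,
ranking class, match result) with the rank-biserial effect size
r = |z| / sqrt(N), and Kruskal-Wallis H across the three FOS categories
with the epsilon-squared effect size eps2 = H (n+1) / (n^2 - 1).
Pairwise follow-ups use Holm's step-down adjustment.  A one-sample
Kolmogorov-Smirnov screen against a moment-matched normal law motivates
the nonparametric choice; Cohen's kappa quantifies inter-rater
agreement of the categorical coding instrument.

The U test's standardized statistic uses the tie-corrected normal
approximation without continuity correction (the convention of the
major commercial statistics packages at these sample sizes); an exact
null distribution is available for small groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.multitest import multipletests

Alpha = float


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group or k-group rank test with its effect size."""

    key: str
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    n_per_group: tuple[int, ...]
    statistic: float  # U (two-group) or H (k-group)
    z_value: float | None
    p_value: float
    effect_size: float  # r for U, eps^2 for H
    effect_kind: Literal["r", "eps2"]


@dataclass(frozen=True)
class ReliabilityResult:
    """Cohen's kappa for one coding criterion."""

    criterion: str
    kappa: float | None  # None: expected agreement = 1, kappa undefined
    n_items: int

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def _clean(values: Sequence[float]) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[~np.isnan(a)]


def mann_whitney_r(
    group_a: Sequence[float],
    group_b: Sequence[float],
    key: str = "",
    labels: tuple[str, str] = ("a", "b"),
    method: Literal["asymptotic", "exact"] = "asymptotic",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test with rank-biserial effect size.

    Missing values (undefined unit rates) are dropped per group.  The
    reported ``statistic`` is U of the first group; ``z_value`` is the
    tie-corrected standardized U (no continuity correction) and
    r = |z| / sqrt(n_a + n_b).  With ``method="exact"`` the p-value
    comes from the exact permutation null instead (ties not supported
    by the exact path).
    """
    a, b = _clean(group_a), _clean(group_b)
    for arr, lab in ((a, labels[0]), (b, labels[1])):
        if arr.size == 0:
            raise ValueError(f"{key or 'comparison'}: group {lab!r} has no defined values")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations tied: no separation
        z = 0.0
        p = 1.0
    else:
        z = (u_a - mu) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    if method == "exact":
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    return ComparisonResult(
        key=key,
        group_labels=labels,
        group_means=(float(a.mean()), float(b.mean())),
        n_per_group=(n_a, n_b),
        statistic=float(u_a),
        z_value=float(z),
        p_value=float(min(p, 1.0)),
        effect_size=float(abs(z) / np.sqrt(n)),
        effect_kind="r",
    )


def kruskal_wallis_eps2(
    groups: Mapping[str, Sequence[float]], key: str = ""
) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H with epsilon-squared effect size.

    eps^2 = H (n + 1) / (n^2 - 1), n = total observations.
    """
    labels = tuple(groups.keys())
    cleaned = [_clean(groups[lab]) for lab in labels]
    for arr, lab in zip(cleaned, labels):
        if arr.size == 0:
            raise ValueError(f"{key or 'comparison'}: group {lab!r} has no defined values")
    n = sum(arr.size for arr in cleaned)
    if np.ptp(np.concatenate(cleaned)) == 0:  # all observations identical
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*cleaned)
    eps2 = h * (n + 1) / (n**2 - 1) if n > 1 else 0.0
    return ComparisonResult(
        key=key,
        group_labels=labels,
        group_means=tuple(float(a.mean()) for a in cleaned),
        n_per_group=tuple(a.size for a in cleaned),
        statistic=float(h),
        z_value=None,
        p_value=float(p),
        effect_size=float(eps2),
        effect_kind="eps2",
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def pairwise_fos_comparisons(
    groups: Mapping[str, Sequence[float]],
    alpha: Alpha = 0.05,
    method: Literal["mwu", "dunn"] = "mwu",
) -> pd.DataFrame:
    """All pairwise comparisons among the three FOS-category groups.

    Default: pairwise Mann-Whitney U tests with Holm adjustment.
    ``method="dunn"`` uses Dunn's z-test on the joint ranking instead
    (the post-hoc paired with Kruskal-Wallis in SPSS).  Returns one row
    per pair with raw and adjusted p and a significance flag at
    ``alpha``.
    """
    labels = list(groups.keys())
    if len(labels) != 3:
        raise ValueError(f"expected exactly three FOS-category groups, got {len(labels)}")
    pairs = list(itertools.combinations(labels, 2))
    rows: list[dict] = []
    if method == "mwu":
        for la, lb in pairs:
            res = mann_whitney_r(groups[la], groups[lb], key=f"{la} vs {lb}", labels=(la, lb))
            rows.append(
                {"pair": f"{la} vs {lb}", "statistic": res.statistic,
                 "z": res.z_value, "p_raw": res.p_value, "effect_size": res.effect_size}
            )
    else:
        cleaned = {lab: _clean(groups[lab]) for lab in labels}
        pooled = np.concatenate([cleaned[lab] for lab in labels])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        mean_ranks, sizes, start = {}, {}, 0
        for lab in labels:
            k = cleaned[lab].size
            mean_ranks[lab] = ranks[start : start + k].mean()
            sizes[lab] = k
            start += k
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
        for la, lb in pairs:
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[la] + 1.0 / sizes[lb]))
            z = (mean_ranks[la] - mean_ranks[lb]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {"pair": f"{la} vs {lb}", "statistic": float(z), "z": float(z),
                 "p_raw": float(p), "effect_size": float(abs(z) / np.sqrt(sizes[la] + sizes[lb]))}
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].tolist())
    out["significant"] = out["p_holm"] < alpha
    return out


def normality_screen(
    variables: Mapping[str, Sequence[float]], alpha: Alpha = 0.05
) -> pd.DataFrame:
    """One-sample KS test of each variable against a moment-matched normal.

    Returns one row per variable: n, KS statistic, p, and a
    ``non_normal`` flag at ``alpha``; constant variables are flagged
    ``degenerate``.  The companion ``attrs["prop_non_normal"]`` gives
    the flagged share, the quantity used to justify a uniformly
    nonparametric battery.
    """
    rows = []
    for name, values in variables.items():
        v = _clean(values)
        if v.size < 3:
            raise ValueError(f"{name}: need >= 3 values for a normality screen, got {v.size}")
        sd = v.std(ddof=1)
        if sd == 0:
            rows.append(
                {"variable": name, "n": v.size, "ks_stat": np.nan, "p_value": np.nan,
                 "non_normal": True, "degenerate": True}
            )
            continue
        stat, p = sps.ks_1samp(v, sps.norm(loc=v.mean(), scale=sd).cdf)
        rows.append(
            {"variable": name, "n": v.size, "ks_stat": float(stat), "p_value": float(p),
             "non_normal": bool(p < alpha), "degenerate": False}
        )
    out = pd.DataFrame(rows)
    out.attrs["prop_non_normal"] = float(out["non_normal"].mean())
    return out


def compare_transitions(
    records: Sequence,
    factor: Literal["gender", "ranking", "result"],
    alpha: Alpha = 0.05,
    ranking_threshold: int = 40,
) -> pd.DataFrame:
    """Mann-Whitney comparison of every transition cell across one factor.

    Units are player-sides (both sides of every match, actor-attributed
    matrices); cell values enter on the percent scale and units whose
    origin row is undefined are dropped for that cell.  Returns one row
    per structurally legal transition: group means, U, z, p, r.
    """
    from .io import derive_covariates
    from .transitions import LEGAL_TRANSITIONS, TRANSIENT_STATES, player_side_matrices

    units = player_side_matrices(records)
    cov = derive_covariates(records, threshold=ranking_threshold)
    column = {"gender": "gender", "ranking": "ranking_class", "result": "result"}[factor]
    label_of = {
        (row.match_id, row.side): getattr(row, column) for row in cov.itertuples()
    }
    levels = sorted({label_of[k] for k in units}, reverse=(factor == "ranking"))
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have two levels, found {levels}")
    rows = []
    for src in TRANSIENT_STATES:
        for dst in LEGAL_TRANSITIONS[src]:
            values: dict[str, list[float]] = {lv: [] for lv in levels}
            for key, matrix in units.items():
                if matrix.origin_totals.loc[src.value] == 0:
                    continue  # undefined row: missing, never zero
                values[label_of[key]].append(100.0 * matrix.cell(src, dst))
            res = mann_whitney_r(
                values[levels[0]],
                values[levels[1]],
                key=f"{src.value} -> {dst.value}",
                labels=(levels[0], levels[1]),
            )
            rows.append(
                {
                    "from_state": src.value,
                    "to_state": dst.value,
                    f"mean_{levels[0]}": res.group_means[0],
                    f"mean_{levels[1]}": res.group_means[1],
                    f"n_{levels[0]}": res.n_per_group[0],
                    f"n_{levels[1]}": res.n_per_group[1],
                    "U": res.statistic,
                    "z": res.z_value,
                    "p_value": res.p_value,
                    "r": res.effect_size,
                    "significant": res.p_value < alpha,
                }
            )
    return pd.DataFrame(rows)


def fos_category_comparison(records: Sequence, alpha: Alpha = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis across FOS categories for every window transition.

    For each match and FOS category, the conditional transition
    probabilities of the four window rows (FOS, FOS+1, FOS+2, FOS+3 to
    continue/P/E) are computed from that match's category-i rallies;
    the three category groups of match-level values (percent scale) are
    then compared with tie-corrected H, epsilon-squared, and
    Holm-adjusted pairwise U tests.
    """
    from .model import ShotState, derive_state_sequence
    from .rates import FOS_CATEGORIES, window_states

    by_match: dict[str, list] = {}
    for rec in records:
        by_match.setdefault(rec.match_id, []).append(derive_state_sequence(rec))

    offsets = ("FOS", "FOS+1", "FOS+2", "FOS+3")
    kinds = ("continue", "P", "E")
    rows = []
    for off_ix, off_name in enumerate(offsets):
        for kind in kinds:
            groups: dict[str, list[float]] = {c: [] for c in FOS_CATEGORIES}
            for seqs in by_match.values():
                for cat in FOS_CATEGORIES:
                    window = window_states(cat)
                    state = window[off_ix]
                    nxt = window[off_ix + 1] if off_ix < 3 else ShotState.OFF
                    cat_seqs = [s for s in seqs if s.fos_state is window[0]]
                    occ = sum(
                        1 for s in cat_seqs if any(sh.state is state for sh in s.shots)
                    )
                    if occ == 0:
                        continue
                    if kind == "continue":
                        hits = sum(
                            1 for s in cat_seqs if any(sh.state is nxt for sh in s.shots)
                        )
                    else:
                        hits = sum(
                            1
                            for s in cat_seqs
                            if s.terminal_state is state and s.outcome is ShotState[kind]
                        )
                    groups[cat].append(100.0 * hits / occ)
            res = kruskal_wallis_eps2(groups, key=f"{off_name} -> {kind}")
            pairwise = pairwise_fos_comparisons(groups, alpha=alpha)
            rows.append(
                {
                    "from_state": off_name,
                    "outcome": kind,
                    **{f"mean_{c}": m for c, m in zip(res.group_labels, res.group_means)},
                    "H": res.statistic,
                    "p_value": res.p_value,
                    "eps2": res.effect_size,
                    "significant": res.p_value < alpha,
                    "significant_pairs": "; ".join(
                        pairwise.loc[pairwise["significant"], "pair"]
                    ),
                }
            )
    return pd.DataFrame(rows)


def cohen_kappa(
    ratings_a: Sequence, ratings_b: Sequence, criterion: str = ""
) -> ReliabilityResult:
    """Unweighted Cohen's kappa, (p_o - p_e) / (1 - p_e), for paired labels.

    When both raters are constant and identical the expected agreement
    is 1 and kappa is undefined (returned as None, never 1).
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("ratings must be paired and non-empty")
    n = len(a)
    # expected agreement from the marginal label distributions
    labels = sorted(set(a) | set(b), key=str)
    pa = np.array([sum(x == lab for x in a) / n for lab in labels])
    pb = np.array([sum(x == lab for x in b) / n for lab in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        return ReliabilityResult(criterion=criterion, kappa=None, n_items=n)
    kappa = float(cohen_kappa_score(a, b))
    return ReliabilityResult(criterion=criterion, kappa=kappa, n_items=n)
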
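"""Statistical procedures: normality gating, paired Wilcoxon feature
selection, repeated-measures ANOVA with sphericity handling, and Bonferroni
post hoc grouping.

The Wilcoxon signed-rank test is the workhorse for feature selection because
per-level features on small cohorts are rarely normal.  For small samples
(``n <= 12`` nonzero differences) the two-sided p-value is computed exactly
by enumerating the null distribution of the positive-rank sum over all sign
assignments (midranks for tied magnitudes are handled by doubling ranks to
integers); larger samples use the normal approximation with tie-corrected
variance and a continuity correction, which is also how the z statistic is
always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .features import ALL_FEATURES, GAME_FEATURES, PUPIL_FEATURES

__all__ = [
    "WilcoxonResult",
    "RmAnovaResult",
    "PosthocResult",
    "FeatureSets",
    "shapiro_gate",
    "wilcoxon_signed_rank",
    "select_features",
    "rm_anova_gg",
    "bonferroni_pairwise",
]

EXACT_THRESHOLD = 12  # largest n for which the exact null is enumerated


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def shapiro_gate(values, alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate for small samples: ``"normal"`` or ``"non_normal"``.

    A constant vector has no distribution to speak of and is routed to the
    nonparametric branch with a warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant input: treating as non-normal", stacklevel=2)
        return "non_normal"
    _, p = sps.shapiro(x)
    return "non_normal" if p < alpha else "normal"


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n: int  # nonzero differences used
    z: float
    p_value: float
    method: str  # "exact" or "approx"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the positive-rank sum given midranks.

    Doubling the midranks makes them integers, so the null distribution of
    the doubled positive-rank sum can be built by dynamic-programming
    convolution over the ``2**n`` equally likely sign assignments.  The
    distribution is symmetric about half the doubled total, so the two-sided
    p doubles the smaller tail (capped at 1).
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on ``x - y`` (or on ``x`` directly).

    Zero differences are dropped (classical treatment); tied magnitudes get
    midranks.  The z statistic uses the tie-corrected variance and a
    continuity correction, signed so that ``x`` systematically below ``y``
    gives a negative z.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mean = n * (n + 1) / 4.0
    # tie correction to the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("degenerate pairing: zero variance")
    dev = w_plus - mean
    cc = 0.5 * np.sign(dev) if dev != 0 else 0.0
    z = float((dev - cc) / np.sqrt(var))
    if n <= EXACT_THRESHOLD:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        method = "approx"
    return WilcoxonResult(w_plus, w_minus, n, z, p, method)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSets:
    """Full and selected feature sets: G (game), P (pupillary)."""

    g: tuple[str, ...] = GAME_FEATURES
    p: tuple[str, ...] = PUPIL_FEATURES
    g_selected: tuple[str, ...] = ()
    p_selected: tuple[str, ...] = ()
    results: dict[str, WilcoxonResult] = field(default_factory=dict)

    @property
    def union_selected(self) -> tuple[str, ...]:
        return self.g_selected + self.p_selected


def select_features(dataset, alpha: float = 0.05) -> FeatureSets:
    """Wilcoxon-based selection of features that separate the two worlds.

    Each participant contributes one value per world and feature — the mean
    over that world's levels — respecting the repeated-measures structure.
    A feature is selected when its paired Wilcoxon p-value is below
    ``alpha``.  Participants lacking records in either world are excluded
    with a warning.
    """
    worlds = sorted(dataset["world"].unique())
    if len(worlds) != 2:
        raise ValueError(f"expected exactly two worlds, found {worlds}")
    means = dataset.groupby(["participant_id", "world"], sort=True)[
        list(ALL_FEATURES)
    ].mean().unstack("world")
    complete = means.notna().all(axis=1)
    if not complete.all():
        dropped = list(means.index[~complete])
        warnings.warn(
            f"participants missing a world excluded from selection: {dropped}",
            stacklevel=2,
        )
        means = means[complete]
    if means.empty:
        raise ValueError("no participant has records in both worlds")
    sets = FeatureSets()
    g_sel, p_sel = [], []
    for feat in ALL_FEATURES:
        a = means[(feat, worlds[0])].to_numpy()
        b = means[(feat, worlds[1])].to_numpy()
        try:
            res = wilcoxon_signed_rank(a, b)
        except ValueError:
            # a feature identical across worlds for everyone carries no signal
            res = WilcoxonResult(0.0, 0.0, 0, 0.0, 1.0, "degenerate")
        sets.results[feat] = res
        # alpha >= 1 is the everything-selected boundary (p can be exactly 1)
        if res.p_value < alpha or alpha >= 1.0:
            (g_sel if feat in GAME_FEATURES else p_sel).append(feat)
    sets.g_selected = tuple(g_sel)
    sets.p_selected = tuple(p_sel)
    return sets


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser handling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmAnovaResult:
    f: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    epsilon_gg: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    sphericity_rejected: bool
    p_value: float  # GG-corrected when sphericity is rejected, else uncorrected


def rm_anova_gg(values, alpha: float = 0.05) -> RmAnovaResult:
    """One-way within-subject ANOVA on a complete subjects x conditions matrix.

    Reports the uncorrected F test, Mauchly's sphericity test (W and its
    chi-square approximation), the Greenhouse-Geisser epsilon, and the
    epsilon-corrected p.  ``p_value`` applies the usual sequential rule:
    the corrected p when Mauchly rejects at ``alpha``, else the uncorrected
    one.  For two conditions epsilon is exactly 1 and sphericity holds
    trivially.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a subjects x conditions matrix")
    s, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if s < k:
        raise ValueError("need at least as many subjects as conditions")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells are not supported (no imputation)")

    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_cond = s * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_cond
    df1 = k - 1.0
    df2 = (k - 1.0) * (s - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        raise ValueError("degenerate data: zero error variance")
    f = float(ms_cond / ms_err)
    p_unc = float(sps.f.sf(f, df1, df2))

    # orthonormal contrasts of the k conditions
    helmert = np.eye(k)[:, : k - 1] - 1.0 / k
    c, _ = np.linalg.qr(helmert)
    cov = np.cov(y, rowvar=False, ddof=1)
    t_mat = c.T @ cov @ c
    eig = np.linalg.eigvalsh(t_mat)
    eig = np.clip(eig, 0, None)
    eps = float(eig.sum() ** 2 / (df1 * np.sum(eig**2)))
    eps = float(np.clip(eps, 1.0 / df1, 1.0))

    if k == 2:
        w = 1.0
        chi2 = 0.0
        m_df = 0
        m_p = 1.0
    else:
        mean_eig = np.trace(t_mat) / df1
        w = float(np.linalg.det(t_mat) / mean_eig ** (k - 1))
        w = min(max(w, np.finfo(float).tiny), 1.0)
        d = k - 1
        d_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (s - 1))
        chi2 = float(-(s - 1) * d_corr * np.log(w))
        m_df = int(k * (k - 1) // 2 - 1)
        # second-order correction to the chi-square approximation
        w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
              / (288.0 * ((s - 1) * d * d_corr) ** 2))
        p1 = sps.chi2.sf(chi2, m_df)
        p2 = sps.chi2.sf(chi2, m_df + 4)
        m_p = float(p1 + w2 * (p2 - p1))

    df1_gg = eps * df1
    df2_gg = eps * df2
    p_gg = float(sps.f.sf(f, df1_gg, df2_gg))
    rejected = bool(m_p < alpha)
    return RmAnovaResult(
        f=f, df1=df1, df2=df2, p_uncorrected=p_unc,
        mauchly_w=w, mauchly_chi2=chi2, mauchly_df=m_df, mauchly_p=m_p,
        epsilon_gg=eps, df1_gg=df1_gg, df2_gg=df2_gg, p_gg=p_gg,
        sphericity_rejected=rejected,
        p_value=p_gg if rejected else p_unc,
    )


# ---------------------------------------------------------------------------
# Bonferroni post hoc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosthocResult:
    conditions: tuple[str, ...]
    p_raw: dict[tuple[str, str], float]
    significant: frozenset[tuple[str, str]]
    groups: tuple[frozenset[str], ...]
    alpha_adjusted: float

    def group_labels(self) -> dict[str, int]:
        """Superscript-style group index for each condition (1-based)."""
        return {c: i + 1 for i, grp in enumerate(self.groups) for c in grp}


def bonferroni_pairwise(values, alpha: float = 0.05,
                        condition_names=None) -> PosthocResult:
    """All pairwise paired t-tests at the Bonferroni-adjusted level.

    ``k`` conditions yield ``k (k - 1) / 2`` comparisons each tested at
    ``alpha`` divided by that count.  Conditions are then grouped as the
    connected components of the graph whose edges join pairs that do *not*
    differ significantly — the usual way superscript group labels are
    assigned in descriptive tables.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("values must be a subjects x conditions matrix, k >= 2")
    k = y.shape[1]
    names = tuple(condition_names) if condition_names is not None \
        else tuple(f"c{i}" for i in range(k))
    if len(names) != k:
        raise ValueError("condition_names length mismatch")
    m = k * (k - 1) // 2
    alpha_adj = alpha / m
    p_raw: dict[tuple[str, str], float] = {}
    sig: set[tuple[str, str]] = set()
    adjacent = {n: set() for n in names}
    for i in range(k):
        for j in range(i + 1, k):
            diff = y[:, i] - y[:, j]
            if np.ptp(diff) == 0:
                p = 1.0 if np.all(diff == 0) else 0.0
            else:
                p = float(sps.ttest_rel(y[:, i], y[:, j]).pvalue)
            pair = (names[i], names[j])
            p_raw[pair] = p
            if p < alpha_adj:
                sig.add(pair)
            else:
                adjacent[names[i]].add(names[j])
                adjacent[names[j]].add(names[i])
    # connected components of the not-significantly-different graph
    groups: list[frozenset[str]] = []
    seen: set[str] = set()
    for name in names:
        if name in seen:
            continue
        stack, comp = [name], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacent[node] - comp)
        seen |= comp
        groups.append(frozenset(comp))
    return PosthocResult(
        conditions=names,
        p_raw=p_raw,
        significant=frozenset(sig),
        groups=tuple(groups),
        alpha_adjusted=alpha_adj,
    )
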
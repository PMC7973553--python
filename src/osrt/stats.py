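"""Behavioral statistics: block rates, effect scores, repeated-measures
ANOVA with Greenhouse-Geisser correction, paired contrasts, and the
random-partition permutation test.

The ANOVA core follows the classical sums-of-squares decomposition for
fully within-subject designs (one or two within factors) and for the mixed
design with one between-group factor. Sphericity is assessed per within
effect with Mauchly's test on orthonormal-contrast-transformed covariance;
when Mauchly's p < 0.05 the reported p-value and degrees of freedom are
Greenhouse-Geisser corrected. Effect sizes are partial eta squared.

The ANOVA is implemented directly on numpy arrays because the partition
test evaluates the two-way within design (anticipation type x block) once
per random partition, typically 10,000 times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import EffectScores

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "PartitionTestResult",
    "block_rates",
    "window_rates",
    "rate_matrix",
    "effect_scores",
    "rm_anova",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "mixed_anova",
    "paired_ttest",
    "pearson_corr",
    "contrast_tests",
    "partition_test",
]

logger = logging.getLogger(__name__)

SEMANTIC_LABELS = ("main", "interference", "stuck", "alternative")


# ---------------------------------------------------------------------------
# Aggregation

def block_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per participant x block anticipation-type rates.

    For each participant and block: the percentage of each semantic label
    among usable (full-prefix, fixation-present) ISIs — the four rates sum
    to 100 — plus the grammatical rate among the same ISIs and the
    correct-anticipation rate among fixation-present ISIs. Blocks without
    usable ISIs yield missing values and are logged.
    """
    rows = []
    for (pid, blk), grp in records.groupby(["participant", "block"], sort=True):
        usable = grp[grp["usable"].astype(bool)]
        n = len(usable)
        row = {"participant": pid, "block": blk, "n_usable": n}
        if n == 0:
            logger.warning("participant %s block %s has no usable ISIs", pid, blk)
            for lab in SEMANTIC_LABELS:
                row[f"pct_{lab}"] = np.nan
            row["pct_grammatical"] = np.nan
        else:
            for lab in SEMANTIC_LABELS:
                row[f"pct_{lab}"] = 100.0 * (usable["semantic"] == lab).sum() / n
            row["pct_grammatical"] = (
                100.0 * (usable["grammatical"] == "grammatical").sum() / n)
        with_fix = grp[grp["stuck_eligible"].astype(bool)]
        row["pct_correct"] = (100.0 * with_fix["correct"].sum() / len(with_fix)
                              if len(with_fix) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def window_rates(records: pd.DataFrame, window_len: int = 12) -> pd.DataFrame:
    """Sequence-resolution rates: semantic-label percentages per consecutive
    ``window_len``-trial window (one underlying sequence cycle each)."""
    rec = records.copy()
    rec["window"] = (rec["trial"] - 1) // window_len + 1
    rows = []
    for (pid, win), grp in rec.groupby(["participant", "window"], sort=True):
        usable = grp[grp["usable"].astype(bool)]
        n = len(usable)
        row = {"participant": pid, "window": win, "block": int(grp["block"].iloc[0]),
               "n_usable": n}
        for lab in SEMANTIC_LABELS:
            row[f"pct_{lab}"] = (100.0 * (usable["semantic"] == lab).sum() / n
                                 if n else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def rate_matrix(rates: pd.DataFrame, column: str,
                index: str = "participant", by: str = "block") -> np.ndarray:
    """Pivot a long rates table into a participants x blocks array."""
    piv = rates.pivot_table(index=index, columns=by, values=column, sort=True)
    return piv.to_numpy()


def effect_scores(block_values, measure: str | None = None) -> EffectScores:
    """Learning / interference / recovery contrasts from per-block values.

    All contrasts are coded chronologically, earlier minus later:
    learning = block 1 - block 6, interference = block 6 - block 7,
    recovery = block 7 - block 8. Missing blocks yield missing scores.

    ``block_values`` maps 1-based block to a value (dict or Series); if a
    DataFrame is given, ``measure`` selects the column and blocks come from
    the ``block`` column.
    """
    if isinstance(block_values, pd.DataFrame):
        block_values = block_values.set_index("block")[measure]
    bv = dict(pd.Series(block_values).items())

    def contrast(earlier, later):
        if earlier in bv and later in bv:
            return float(bv[earlier]) - float(bv[later])
        return None

    learning = contrast(1, 6)
    if learning is None:
        raise ValueError("blocks 1 and 6 are required for the learning score")
    return EffectScores(learning=learning,
                        interference=contrast(6, 7),
                        recovery=contrast(7, 8))


# ---------------------------------------------------------------------------
# ANOVA core

@dataclass(frozen=True)
class AnovaResult:
    """One ANOVA effect.

    ``p`` is the reported p-value: Greenhouse-Geisser corrected when the
    effect's Mauchly test was significant (p < 0.05), uncorrected
    otherwise; ``df1``/``df2`` follow the same convention, so corrected
    denominators are fractional. ``eps`` is the GG epsilon (1.0 for
    between effects and two-level within effects, where sphericity is
    vacuous).
    """

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    p_unc: float
    eta_p2: float
    eps: float = 1.0
    mauchly_p: float = 1.0
    corrected: bool = False


def _helmert(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, (k-1) x k rows orthogonal to the mean."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_eps(S: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a condition covariance matrix and an
    orthonormal contrast for the effect."""
    Sc = C @ S @ C.T
    d = Sc.shape[0]
    if d == 0:
        return 1.0
    tr = np.trace(Sc)
    denom = d * np.sum(Sc * Sc)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / d, 1.0))


def _mauchly_p(S: np.ndarray, C: np.ndarray, n_eff: int) -> float:
    """Mauchly's sphericity test on the contrast-transformed covariance.

    ``n_eff`` is the error df of the covariance estimate (n-1 for a single
    sample, N-G pooled across groups). Returns 1.0 when the test is vacuous
    (fewer than two contrast dimensions or too few subjects).
    """
    Sc = C @ S @ C.T
    d = Sc.shape[0]
    if d < 2 or n_eff <= d:
        return 1.0
    det = np.linalg.det(Sc)
    tr = np.trace(Sc)
    if det <= 0 or tr <= 0:
        return 0.0
    W = det / (tr / d) ** d
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * n_eff)
    chi2 = -n_eff * f * np.log(W)
    df = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(chi2, df))


def _within_result(effect: str, ss_eff: float, df1: int, ss_err: float, df2: int,
                   S: np.ndarray, C: np.ndarray, n_eff: int) -> AnovaResult:
    if ss_err > 1e-12:
        F = (ss_eff / df1) / (ss_err / df2)
    else:
        F = 0.0 if ss_eff <= 1e-12 else np.inf
    p_unc = float(sps.f.sf(F, df1, df2))
    eps = _gg_eps(S, C)
    mau = _mauchly_p(S, C, n_eff)
    corrected = mau < 0.05 and C.shape[0] > 1
    if corrected:
        d1, d2 = eps * df1, eps * df2
        p = float(sps.f.sf(F, d1, d2))
    else:
        d1, d2, p = float(df1), float(df2), p_unc
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(effect=effect, F=float(F), df1=d1, df2=d2, p=p, p_unc=p_unc,
                       eta_p2=float(eta), eps=eps, mauchly_p=mau, corrected=corrected)


def rm_anova_oneway(X: np.ndarray, effect: str = "within") -> AnovaResult:
    """One-way repeated-measures ANOVA on an n-subject x k-level array."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < 2:
        raise ValueError("at least 2 participants are required")
    g = X.mean()
    ss_factor = n * np.sum((X.mean(0) - g) ** 2)
    ss_subj = k * np.sum((X.mean(1) - g) ** 2)
    ss_total = np.sum((X - g) ** 2)
    ss_err = ss_total - ss_factor - ss_subj
    S = np.cov(X, rowvar=False)
    C = _helmert(k)
    return _within_result(effect, ss_factor, k - 1, ss_err, (n - 1) * (k - 1),
                          S, C, n - 1)


def rm_anova_twoway(X: np.ndarray, names: tuple[str, str] = ("A", "B")) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA on an n x a x b array.

    Returns results for the two main effects and the interaction, each
    tested against its own subject-interaction error term with its own
    sphericity assessment.
    """
    X = np.asarray(X, dtype=float)
    n, a, b = X.shape
    if n < 2:
        raise ValueError("at least 2 participants are required")
    g = X.mean()
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_ab = X.mean(axis=0)
    m_s = X.mean(axis=(1, 2))
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)

    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_s = a * b * np.sum((m_s - g) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    ss_total = np.sum((X - g) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    C_a, C_b = _helmert(a), _helmert(b)
    S_a = np.cov(m_sa, rowvar=False)
    S_b = np.cov(m_sb, rowvar=False)
    S_ab = np.cov(X.reshape(n, a * b), rowvar=False)
    C_ab = np.kron(C_a, C_b)

    return [
        _within_result(names[0], ss_a, a - 1, ss_as, (n - 1) * (a - 1),
                       np.atleast_2d(S_a), C_a, n - 1),
        _within_result(names[1], ss_b, b - 1, ss_bs, (n - 1) * (b - 1),
                       np.atleast_2d(S_b), C_b, n - 1),
        _within_result(f"{names[0]}*{names[1]}", ss_ab, (a - 1) * (b - 1),
                       ss_abs, (n - 1) * (a - 1) * (b - 1),
                       S_ab, C_ab, n - 1),
    ]


def mixed_anova(groups: list[np.ndarray],
                names: tuple[str, str] = ("group", "within")) -> list[AnovaResult]:
    """Mixed ANOVA: one between-group factor, one within factor.

    ``groups`` is a list of n_g x k arrays, one per group (unbalanced group
    sizes allowed). Sphericity uses the covariance pooled across groups
    with N - G error df.
    """
    groups = [np.asarray(gr, dtype=float) for gr in groups]
    k = groups[0].shape[1]
    if any(gr.shape[1] != k for gr in groups):
        raise ValueError("all groups must share the within-factor levels")
    if any(gr.shape[0] < 2 for gr in groups):
        raise ValueError("at least 2 participants per group are required")
    G = len(groups)
    ns = np.array([gr.shape[0] for gr in groups])
    N = int(ns.sum())
    allX = np.vstack(groups)
    grand = allX.mean()
    rowm = allX.mean(axis=1)
    colm = allX.mean(axis=0)
    gm = np.array([gr.mean() for gr in groups])

    ss_total = np.sum((allX - grand) ** 2)
    ss_between_subj = k * np.sum((rowm - grand) ** 2)
    ss_group = k * np.sum(ns * (gm - grand) ** 2)
    ss_err_between = ss_between_subj - ss_group
    ss_time = N * np.sum((colm - grand) ** 2)
    ss_inter = 0.0
    for gr, gmean, n_g in zip(groups, gm, ns):
        cell = gr.mean(axis=0)
        ss_inter += n_g * np.sum((cell - gmean - colm + grand) ** 2)
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_inter

    df_g, df_eg = G - 1, N - G
    df_t, df_i, df_ew = k - 1, (G - 1) * (k - 1), (N - G) * (k - 1)

    F_g = (ss_group / df_g) / (ss_err_between / df_eg)
    p_g = float(sps.f.sf(F_g, df_g, df_eg))
    between = AnovaResult(effect=names[0], F=float(F_g), df1=float(df_g),
                          df2=float(df_eg), p=p_g, p_unc=p_g,
                          eta_p2=float(ss_group / (ss_group + ss_err_between)))

    S_pool = sum((n_g - 1) * np.cov(gr, rowvar=False)
                 for gr, n_g in zip(groups, ns)) / (N - G)
    C = _helmert(k)
    within = _within_result(names[1], ss_time, df_t, ss_err_within, df_ew,
                            S_pool, C, N - G)
    interaction = _within_result(f"{names[0]}*{names[1]}", ss_inter, df_i,
                                 ss_err_within, df_ew, S_pool, C, N - G)
    return [between, within, interaction]


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: str | list[str], between: str | None = None) -> pd.DataFrame:
    """Repeated-measures / mixed ANOVA on a long-format table.

    ``within`` names one or two within-subject factor columns; ``between``
    optionally names a group column (only with a single within factor).
    Subjects with missing cells are dropped listwise (logged). Returns one
    row per effect with the fields of :class:`AnovaResult`.
    """
    if isinstance(within, str):
        within = [within]
    cols = [subject, dv] + within + ([between] if between else [])
    d = data[cols].copy()
    complete = d.dropna()
    dropped = set(d[subject]) - set(complete[subject].unique())
    wide_ok = []
    n_cells = int(np.prod([complete[w].nunique() for w in within]))
    for pid, grp in complete.groupby(subject):
        if len(grp) == n_cells:
            wide_ok.append(pid)
        else:
            dropped.add(pid)
    if dropped:
        logger.info("listwise deletion dropped %d participant(s): %s",
                    len(dropped), sorted(map(str, dropped)))
    d = complete[complete[subject].isin(wide_ok)]

    if between is None and len(within) == 1:
        piv = d.pivot_table(index=subject, columns=within[0], values=dv, sort=True)
        results = [rm_anova_oneway(piv.to_numpy(), effect=within[0])]
    elif between is None and len(within) == 2:
        a_lv = sorted(d[within[0]].unique())
        b_lv = sorted(d[within[1]].unique())
        piv = d.pivot_table(index=subject, columns=within, values=dv, sort=True)
        X = piv.to_numpy().reshape(len(piv), len(a_lv), len(b_lv))
        results = rm_anova_twoway(X, names=(within[0], within[1]))
    elif between is not None and len(within) == 1:
        arrays = []
        for _, grp in d.groupby(between, sort=True):
            piv = grp.pivot_table(index=subject, columns=within[0], values=dv, sort=True)
            arrays.append(piv.to_numpy())
        results = mixed_anova(arrays, names=(between, within[0]))
    else:
        raise ValueError("supported designs: 1-2 within factors, optional "
                         "between factor with a single within factor")
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Contrasts

@dataclass(frozen=True)
class ContrastResult:
    """A paired t-test (two-tailed) or Pearson correlation."""

    kind: str          # "ttest" | "correlation"
    statistic: float   # t or r
    df: int
    p: float


def paired_ttest(a, b) -> ContrastResult:
    """Paired two-tailed t-test; df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("at least 3 pairs are required")
    d = a - b
    if np.all(d == 0):  # identical vectors: no evidence of a difference
        return ContrastResult(kind="ttest", statistic=0.0, df=len(a) - 1, p=1.0)
    res = sps.ttest_rel(a, b)
    return ContrastResult(kind="ttest", statistic=float(res.statistic),
                          df=len(a) - 1, p=float(res.pvalue))


def pearson_corr(a, b) -> ContrastResult:
    """Pearson correlation; df = n - 2. Zero variance raises ValueError."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("at least 3 pairs are required")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(a, b)
    return ContrastResult(kind="correlation", statistic=float(r),
                          df=len(a) - 2, p=float(p))


def contrast_tests(a, b, mode: str = "ttest") -> ContrastResult:
    """Paired contrast dispatcher: ``mode`` is ``ttest`` or ``correlation``."""
    if mode == "ttest":
        return paired_ttest(a, b)
    if mode == "correlation":
        return pearson_corr(a, b)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Partition permutation test

@dataclass(frozen=True)
class PartitionTestResult:
    """Proportions of random half/half partitions with significant effects."""

    prop_main_significant: float
    prop_interaction_significant: float
    n_partitions: int
    n_participants: int
    alpha: float


def partition_test(rates_a: np.ndarray, rates_b: np.ndarray,
                   n_partitions: int = 10000, seed: int | None = None,
                   alpha: float = 0.05) -> PartitionTestResult:
    """Random-partition calibration of the two grammatical-label series.

    Each participant contributes two per-block rate series: fixations
    matching sequence A's successor (``rates_a``, n x blocks) and sequence
    B's (``rates_b``). For each random half/half partition one half treats
    A as the Main sequence (main = A-series, interference = B-series), the
    other half the reverse; a two-way within ANOVA (anticipation type x
    block) is run and the main effect of type and the type x block
    interaction are tested at ``alpha`` (Greenhouse-Geisser corrected when
    Mauchly's test is significant). Returns the two significant
    proportions; reproducible under a fixed seed.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    A = np.asarray(rates_a, dtype=float)
    B = np.asarray(rates_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("rates_a and rates_b must be equal-shape n x blocks arrays")
    n = A.shape[0]
    half = n // 2
    if n % 2:
        logger.info("odd participant count %d: halves of %d and %d", n, half, n - half)
    rng = np.random.default_rng(seed)
    stacked_a = np.stack([A, B], axis=1)  # participant treated as A-as-main
    stacked_b = np.stack([B, A], axis=1)

    sig_main = sig_inter = 0
    for _ in range(n_partitions):
        perm = rng.permutation(n)
        a_half = np.zeros(n, dtype=bool)
        a_half[perm[:half]] = True
        X = np.where(a_half[:, None, None], stacked_a, stacked_b)
        res_type, _, res_inter = rm_anova_twoway(X, names=("type", "block"))
        sig_main += res_type.p < alpha
        sig_inter += res_inter.p < alpha
    return PartitionTestResult(
        prop_main_significant=sig_main / n_partitions,
        prop_interaction_significant=sig_inter / n_partitions,
        n_partitions=n_partitions, n_participants=n, alpha=alpha,
    )
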
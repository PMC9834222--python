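"""Significance testing for allelic imbalance.

Within-sample significance uses an exact binomial test of the major
allele count against an empirical null probability p0 — the median of
per-sample median ASE scores — rather than 0.5, so that cohort-wide
technical skew (reference bias, mapping artifacts) is absorbed into the
null. Multiple testing is controlled with Benjamini-Hochberg, by default
within each sample to match per-individual reporting.

Between-group comparisons of per-SNP score vectors use the Wilcoxon
rank-sum test (each group vs the rest) and the Kruskal-Wallis test
(omnibus across all groups); both are non-parametric because ASE scores
are non-normal and measurements per SNP are sparse.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NOT_TESTABLE = float("nan")


@dataclass
class NullProbability:
    """Empirical null major-allele probability.

    ``p0`` is the median over samples of each sample's median retained
    ASE score (midpoint interpolation for even lengths).
    """

    p0: float
    per_sample_medians: dict[str, float]


def estimate_null_probability(retained: pd.DataFrame) -> NullProbability:
    """Median-of-medians null from retained scored records."""
    if len(retained) == 0:
        raise ValueError("no retained records to estimate the null from")
    medians = retained.groupby("sample_id")["ase_score"].median()
    return NullProbability(
        p0=float(medians.median()),
        per_sample_medians=medians.to_dict(),
    )


def binomial_ase_test(ref_count, alt_count, p0: float, alternative: str = "greater"):
    """Exact binomial p-value for allelic imbalance at one locus.

    Tests k = max(ref, alt) against Binomial(n = ref + alt, p0). The
    default one-sided upper tail P[X >= k] asks for *more* imbalance than
    the empirical background; ``alternative="two-sided"`` doubles the
    smaller tail (capped at 1). Vectorized over count arrays.
    """
    if not 0.5 <= p0 < 1.0:
        raise ValueError(f"p0 must be in [0.5, 1), got {p0}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    n = ref + alt
    if np.any(n < 1):
        raise ValueError("ref_count + alt_count must be >= 1")
    k = np.maximum(ref, alt)
    upper = sps.binom.sf(k - 1, n, p0)
    if alternative == "greater":
        p = upper
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(upper, sps.binom.cdf(k, n, p0)))
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(p)
    return p


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_records(
    retained: pd.DataFrame,
    p0: float | None = None,
    bh_scope: str = "sample",
    alternative: str = "greater",
) -> tuple[pd.DataFrame, NullProbability]:
    """Test every retained record for imbalance and attach p/q columns.

    Parameters
    ----------
    p0
        Null major-allele probability; estimated from the data
        (median of per-sample medians) when None.
    bh_scope
        "sample" corrects within each sample (matches per-individual
        reporting); "global" corrects across the whole table.
    """
    if bh_scope not in ("sample", "global"):
        raise ValueError(f"bh_scope must be 'sample' or 'global', got {bh_scope!r}")
    if p0 is None:
        null = estimate_null_probability(retained)
    else:
        null = NullProbability(p0=float(p0), per_sample_medians={})
    out = retained.copy()
    out["p_value"] = binomial_ase_test(
        out["ref_count"].to_numpy(), out["alt_count"].to_numpy(),
        null.p0, alternative=alternative,
    )
    if bh_scope == "global":
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    else:
        out["q_value"] = (
            out.groupby("sample_id")["p_value"].transform(lambda p: adjust_bh(p.to_numpy()))
        )
    logger.info(
        "tested %d records against p0=%.4f (BH scope: %s)",
        len(out), null.p0, bh_scope,
    )
    return out, null


def _pooled(scores_by_group: Mapping[str, Sequence[float]], exclude=None) -> np.ndarray:
    return np.concatenate(
        [np.asarray(v, dtype=float) for g, v in scores_by_group.items() if g != exclude]
        or [np.empty(0)]
    )


def group_test_one_vs_rest(
    scores_by_group: Mapping[str, Sequence[float]],
    target_group: str,
    min_per_side: int = 3,
) -> float:
    """Two-sided Wilcoxon rank-sum p of one group vs all others pooled.

    Uses the exact null distribution when both sides have <= 10
    observations and no ties, otherwise the tie-corrected normal
    approximation (no continuity correction). Returns NaN (not testable)
    when either side has fewer than ``min_per_side`` observations.
    """
    if target_group not in scores_by_group:
        raise ValueError(f"unknown target group: {target_group!r}")
    x = np.asarray(scores_by_group[target_group], dtype=float)
    y = _pooled(scores_by_group, exclude=target_group)
    if len(x) < min_per_side or len(y) < min_per_side:
        return NOT_TESTABLE
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def kruskal_h(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        offset += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def _partitions(indices: np.ndarray, sizes: Sequence[int]):
    """All ways to split ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for head in itertools.combinations(indices, sizes[0]):
        rest = np.array(sorted(set(indices) - set(head)), dtype=int)
        for tail in _partitions(rest, sizes[1:]):
            yield (head,) + tail


def group_test_omnibus(
    scores_by_group: Mapping[str, Sequence[float]],
    min_per_group: int = 3,
    method: str = "chi2",
) -> float:
    """Kruskal-Wallis p-value for score differences across all groups.

    With ``method="chi2"`` (default) the tie-corrected H statistic is
    referred to a chi-squared distribution with (groups - 1) degrees of
    freedom. ``method="exact"`` enumerates the permutation distribution
    of H instead (only feasible for small totals) and returns
    P[H_perm >= H_obs]. Returns NaN when fewer than two groups have data
    or any present group has fewer than ``min_per_group`` observations.
    """
    if method not in ("chi2", "exact"):
        raise ValueError(f"unknown method: {method!r}")
    groups = [np.asarray(v, dtype=float) for v in scores_by_group.values() if len(v) > 0]
    if len(groups) < 2:
        return NOT_TESTABLE
    if any(len(g) < min_per_group for g in groups):
        return NOT_TESTABLE
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    if method == "chi2":
        return float(sps.kruskal(*groups).pvalue)
    sizes = [len(g) for g in groups]
    h_obs = kruskal_h(groups)
    n_ge = 0
    n_total = 0
    for part in _partitions(np.arange(len(pooled)), sizes):
        h = kruskal_h([pooled[list(idx)] for idx in part])
        n_total += 1
        if h >= h_obs - 1e-12:
            n_ge += 1
    return n_ge / n_total


def compare_groups(
    retained: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "both",
    min_per_side: int = 3,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Per-SNP group comparison table (one-vs-rest and/or omnibus).

    ``retained`` must carry sample_id, variant_id, contig, position and
    ase_score (one measurement per sample per SNP); group labels come
    from ``metadata``. Within each comparison, BH adjustment runs across
    all testable SNPs; untestable entries stay NaN.
    """
    if mode not in ("one-vs-rest", "omnibus", "both"):
        raise ValueError(f"unknown mode: {mode!r}")
    merged = retained.merge(
        metadata[["sample_id", "group_label"]], on="sample_id", how="inner"
    )
    group_order = sorted(metadata["group_label"].unique())
    rows = []
    for (variant_id, contig, position), snp in merged.groupby(
        ["variant_id", "contig", "position"], sort=True
    ):
        by_group = {
            g: snp.loc[snp["group_label"] == g, "ase_score"].to_numpy()
            for g in group_order
        }
        row: dict = {"variant_id": variant_id, "contig": contig, "position": position}
        for g in group_order:
            row[f"n_{g}"] = len(by_group[g])
        if mode in ("one-vs-rest", "both"):
            for g in group_order:
                row[f"p_{g}_vs_rest"] = group_test_one_vs_rest(
                    by_group, g, min_per_side=min_per_side
                )
        if mode in ("omnibus", "both"):
            row["omnibus_p"] = group_test_omnibus(
                by_group, min_per_group=min_per_group
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    p_cols = [c for c in out.columns if c.startswith("p_") or c == "omnibus_p"]
    for col in p_cols:
        qcol = "omnibus_q" if col == "omnibus_p" else "q" + col[1:]
        q = np.full(len(out), np.nan)
        testable = out[col].notna().to_numpy()
        if testable.any():
            q[testable] = adjust_bh(out.loc[testable, col].to_numpy())
        out[qcol] = q
    return out


def qq_inflation(
    p_subset: Sequence[float], p_rest: Sequence[float]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Observed-vs-expected -log10 p quantiles for two p-value lists.

    Each list is sorted ascending against uniform expected quantiles
    i/(m+1). Returns a long-format table (membership, expected_neglog10,
    observed_neglog10) and per-list inflation factors lambda = median
    observed chi-squared quantile / median expected quantile.
    """
    frames = []
    lambdas: dict[str, float] = {}
    for name, values in (("subset", p_subset), ("rest", p_rest)):
        p = np.sort(np.asarray(values, dtype=float))
        if p.size == 0:
            raise ValueError(f"p-value list '{name}' is empty")
        expected = np.arange(1, p.size + 1) / (p.size + 1)
        frames.append(
            pd.DataFrame(
                {
                    "membership": name,
                    "expected_neglog10": -np.log10(expected),
                    "observed_neglog10": -np.log10(p),
                }
            )
        )
        lambdas[name] = float(
            np.median(sps.chi2.isf(p, df=1))
            / sps.chi2.isf(np.median(expected), df=1)
        )
    return pd.concat(frames, ignore_index=True), lambdas


def gene_subset_hit_rate(
    gene_table: pd.DataFrame, subset: Iterable[str], q_cutoff: float = 0.05
) -> tuple[float, float]:
    """Fraction of significant (gene, sample) rows inside vs outside a subset.

    A row is a hit when its ``best_q`` < ``q_cutoff``. Returns
    (rate_subset, rate_rest); rate_subset is NaN when the subset matches
    no rows.
    """
    subset = set(subset)
    inside = gene_table["gene_id"].isin(subset)
    hits = gene_table["best_q"] < q_cutoff
    if not subset or not inside.any():
        if subset:
            logger.warning("gene subset matches no rows of the gene table")
        rate_subset = float("nan")
    else:
        rate_subset = float(hits[inside].mean())
    rate_rest = float(hits[~inside].mean()) if (~inside).any() else float("nan")
    return rate_subset, rate_rest


def gene_set_overlap_test(
    hit_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation_set: Iterable[str],
) -> tuple[float, float]:
    """One-sided hypergeometric enrichment of hits in an annotation set.

    Tests |hit ∩ annotation| against drawing |hit| genes from the
    background. Returns (p_value, fold_enrichment) where fold is the
    observed/expected overlap.
    """
    hit = set(hit_genes)
    background = set(background_genes)
    if not hit <= background:
        raise ValueError("hit_genes must be a subset of background_genes")
    annotated = set(annotation_set) & background
    n_bg = len(background)
    n_ann = len(annotated)
    n_hit = len(hit)
    k = len(hit & annotated)
    p = float(sps.hypergeom.sf(k - 1, n_bg, n_ann, n_hit))
    expected = n_hit * n_ann / n_bg if n_bg else float("nan")
    fold = k / expected if expected > 0 else float("nan")
    return p, fold
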
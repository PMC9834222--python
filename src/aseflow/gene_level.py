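"""Gene-level summaries of SNP-level imbalance results.

Because several ASE mechanisms (splicing, NMD-truncated transcripts)
are position-specific, per-gene aggregation of scores would dilute true
signal; instead the SNP with the lowest p-value represents the gene for
each individual, and cohort-level sharing is counted on top of that.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from aseflow import io_formats

logger = logging.getLogger(__name__)

GENE_ROW_COLUMNS = [
    "sample_id",
    "gene_id",
    "gene_symbol",
    "best_variant_id",
    "best_p",
    "best_q",
    "best_ase_score",
    "n_snps_in_gene",
]


def best_snp_per_gene(tested: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Pick the representative (lowest-p) SNP per sample x gene.

    SNPs mapping to multiple genes contribute to each of them; ties on p
    are broken by lower q, then lexicographically smallest variant_id.
    Unmapped SNPs are counted and logged.
    """
    if len(mapping) == 0:
        raise ValueError("SNP-gene mapping is empty")
    merged = tested.merge(
        mapping[["variant_id", "gene_id", "gene_symbol"]], on="variant_id", how="inner"
    )
    n_unmapped = tested.loc[
        ~tested["variant_id"].isin(set(mapping["variant_id"]))
    ].shape[0]
    if n_unmapped:
        logger.info("best_snp_per_gene: %d tested records had no gene mapping", n_unmapped)
    if len(merged) == 0:
        return pd.DataFrame(columns=GENE_ROW_COLUMNS)
    merged = merged.sort_values(
        ["sample_id", "gene_id", "p_value", "q_value", "variant_id"],
        kind="mergesort",
    )
    grouped = merged.groupby(["sample_id", "gene_id"], sort=True)
    # row-wise first (drop_duplicates), not column-wise first-non-null
    best = merged.drop_duplicates(subset=["sample_id", "gene_id"], keep="first")
    n_snps = grouped["variant_id"].nunique().reset_index(name="n_snps_in_gene")
    best = best.merge(n_snps, on=["sample_id", "gene_id"])
    best = best.rename(
        columns={
            "variant_id": "best_variant_id",
            "p_value": "best_p",
            "q_value": "best_q",
            "ase_score": "best_ase_score",
        }
    )
    return best[GENE_ROW_COLUMNS].reset_index(drop=True)


def shared_imbalance(gene_rows: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Count, per gene, the samples with significant imbalance.

    A sample counts as imbalanced for a gene when its representative
    SNP's ``best_q`` < ``q_cutoff``; genes never significant are kept
    (with count 0) so downstream set operations see the full background.
    Sorted by count descending, then gene_id ascending.
    """
    if not 0 < q_cutoff < 1:
        raise ValueError(f"q_cutoff must be in (0, 1), got {q_cutoff}")
    grouped = gene_rows.groupby(["gene_id", "gene_symbol"], sort=True)
    out = grouped.agg(
        n_samples_imbalanced=("best_q", lambda q: int((q < q_cutoff).sum())),
        n_samples_measured=("sample_id", "nunique"),
    ).reset_index()
    out = out.sort_values(
        ["n_samples_imbalanced", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def per_sample_significance_summary(
    tested: pd.DataFrame, q_cutoff: float = 0.05
) -> pd.DataFrame:
    """SNP-level significant counts and percentages per sample."""
    if not 0 < q_cutoff < 1:
        raise ValueError(f"q_cutoff must be in (0, 1), got {q_cutoff}")
    grouped = tested.groupby("sample_id", sort=True)
    out = grouped.agg(
        n_tested=("q_value", "size"),
        n_significant=("q_value", lambda q: int((q < q_cutoff).sum())),
    ).reset_index()
    out["percent_significant"] = 100.0 * out["n_significant"] / out["n_tested"]
    return out


def export_gene_lists(
    gene_rows: pd.DataFrame, out_dir, q_cutoff: float = 0.05
) -> tuple[Path, Path]:
    """Write significant and background gene lists for external GO tools.

    A gene is significant when its best q in any sample is below the
    cutoff; the background is every gene with at least one measurement.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    significant = set(gene_rows.loc[gene_rows["best_q"] < q_cutoff, "gene_id"])
    background = set(gene_rows["gene_id"])
    sig_path = out_dir / "significant_genes.txt"
    bg_path = out_dir / "background_genes.txt"
    io_formats.write_gene_list(significant, sig_path)
    io_formats.write_gene_list(background, bg_path)
    return sig_path, bg_path
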
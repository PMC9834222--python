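"""Synthetic ASE cohorts with known ground truth.

Emulates the structure the pipeline assumes: per (sample, locus) pairs
that are either heterozygous (allele counts near 50/50, or skewed where
an imbalance effect is planted) or homozygous (monoallelic expression
plus a small sequencing-error leak of minor-allele reads), overdispersed
negative-binomial read depth, sparse per-SNP coverage across samples,
and genotypes available for only part of the cohort.

Defaults mirror a genotype-assisted bulk RNA-seq ASE study: ~80% of
calibration pairs homozygous, 1% sequencing-error rate at homozygous
loci, mean depth 50 with strong overdispersion, 30% missingness, 40% of
samples genotyped, and four patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from aseflow.io_formats import ZYGOSITY_HET, ZYGOSITY_HOM

_BASES = ("A", "C", "G", "T")

ImbalanceSpec = Mapping[int, Union[float, Mapping[str, float]]]


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    Attributes
    ----------
    fraction_hom
        Probability that a (sample, locus) pair is homozygous.
    hom_error_rate
        Minor-allele read probability at homozygous pairs (sequencing
        error / mismapping leak).
    depth_mean, depth_dispersion
        Negative-binomial read-depth model (floor 1); dispersion is the
        NB size parameter, smaller = more overdispersed.
    baseline_het_p
        Major-allele probability at unplanted heterozygous pairs.
    imbalanced_loci
        Locus index -> major-allele probability, either a single float
        (applies to every sample) or a mapping group_label -> probability
        (unlisted groups stay at baseline).
    group_labels
        sample_id -> group label; by default ``n_groups`` groups assigned
        round-robin.
    missingness
        Probability that a (sample, locus) pair is unmeasured.
    genotyped_fraction
        Leading fraction of samples that receive truthful VCF genotypes.
    snps_per_gene
        Loci per synthetic gene in the emitted SNP-gene map.
    """

    n_samples: int = 40
    n_loci: int = 2000
    fraction_hom: float = 0.8
    hom_error_rate: float = 0.01
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    baseline_het_p: float = 0.5
    imbalanced_loci: ImbalanceSpec = field(default_factory=dict)
    group_labels: Mapping[str, str] | None = None
    n_groups: int = 4
    missingness: float = 0.3
    genotyped_fraction: float = 0.4
    snps_per_gene: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        def check(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ValueError(f"invalid CohortSpec.{name}: {why}")

        check(self.n_samples >= 1, "n_samples", "must be >= 1")
        check(self.n_loci >= 1, "n_loci", "must be >= 1")
        check(0.0 <= self.fraction_hom <= 1.0, "fraction_hom", "must be in [0, 1]")
        check(0.0 < self.hom_error_rate < 0.5, "hom_error_rate", "must be in (0, 0.5)")
        check(self.depth_mean > 0, "depth_mean", "must be > 0")
        check(self.depth_dispersion > 0, "depth_dispersion", "must be > 0")
        check(0.0 < self.baseline_het_p < 1.0, "baseline_het_p", "must be in (0, 1)")
        check(0.0 <= self.missingness <= 1.0, "missingness", "must be in [0, 1]")
        check(
            0.0 <= self.genotyped_fraction <= 1.0,
            "genotyped_fraction", "must be in [0, 1]",
        )
        check(self.snps_per_gene >= 1, "snps_per_gene", "must be >= 1")
        check(self.n_groups >= 1, "n_groups", "must be >= 1")
        for locus, effect in dict(self.imbalanced_loci).items():
            check(
                0 <= int(locus) < self.n_loci,
                "imbalanced_loci", f"locus index {locus} out of range",
            )
            probs = [effect] if isinstance(effect, (int, float)) else list(effect.values())
            for p in probs:
                check(0.0 < p < 1.0, "imbalanced_loci", f"probability {p} not in (0, 1)")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def resolved_groups(self) -> dict[str, str]:
        if self.group_labels is not None:
            groups = dict(self.group_labels)
            missing = [s for s in self.sample_ids if s not in groups]
            if missing:
                raise ValueError(
                    f"invalid CohortSpec.group_labels: no label for {missing[:5]}"
                )
            return groups
        return {
            sid: f"G{(i % self.n_groups) + 1}"
            for i, sid in enumerate(self.sample_ids)
        }


@dataclass
class SyntheticCohort:
    """In-memory result of :func:`simulate_cohort` (all long DataFrames)."""

    spec: CohortSpec
    counts: pd.DataFrame      # allele-count contract (measured pairs only)
    genotypes: pd.DataFrame   # genotype-call contract (genotyped samples)
    metadata: pd.DataFrame    # sample_id, group_label, genotyped
    truth: pd.DataFrame       # per (sample, locus) ground truth
    snp_gene_map: pd.DataFrame


def _locus_table(spec: CohortSpec) -> pd.DataFrame:
    idx = np.arange(spec.n_loci)
    contig = (idx * 22) // spec.n_loci + 1
    first_on_contig = np.r_[0, np.flatnonzero(np.diff(contig)) + 1]
    offset = np.repeat(first_on_contig, np.diff(np.r_[first_on_contig, spec.n_loci]))
    position = (idx - offset + 1) * 100
    return pd.DataFrame(
        {
            "locus": idx,
            "contig": contig.astype(str),
            "position": position,
            "variant_id": [f"rs{100000 + i}" for i in idx],
            "ref_allele": [_BASES[i % 4] for i in idx],
            "alt_allele": [_BASES[(i + 1) % 4] for i in idx],
        }
    )


def simulate_cohort(spec: CohortSpec, out_dir=None) -> SyntheticCohort:
    """Draw a full cohort; optionally write it to disk (see write_cohort).

    Fully deterministic given ``spec.seed``. The truth table covers every
    (sample, locus) pair — including unmeasured ones — with its zygosity,
    true major-allele probability, planted flag and measured flag.
    """
    rng = np.random.default_rng(spec.seed)
    S, L = spec.n_samples, spec.n_loci
    loci = _locus_table(spec)
    samples = spec.sample_ids
    groups = spec.resolved_groups()

    is_hom = rng.random((S, L)) < spec.fraction_hom
    nb_p = spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean)
    depth = np.maximum(
        1, rng.negative_binomial(spec.depth_dispersion, nb_p, size=(S, L))
    )

    p_major = np.full((S, L), spec.baseline_het_p)
    planted_loci = np.zeros(L, dtype=bool)
    for locus, effect in dict(spec.imbalanced_loci).items():
        locus = int(locus)
        planted_loci[locus] = True
        if isinstance(effect, (int, float)):
            p_major[:, locus] = float(effect)
        else:
            for i, sid in enumerate(samples):
                p_major[i, locus] = float(effect.get(groups[sid], spec.baseline_het_p))

    # fold direction is irrelevant to the score; randomize which allele
    # is the major / expressed one per (sample, locus)
    ref_is_major = rng.random((S, L)) < 0.5
    p_ref_het = np.where(ref_is_major, p_major, 1.0 - p_major)
    p_ref_hom = np.where(
        ref_is_major, 1.0 - spec.hom_error_rate, spec.hom_error_rate
    )
    p_ref = np.where(is_hom, p_ref_hom, p_ref_het)
    ref_count = rng.binomial(depth, p_ref)
    alt_count = depth - ref_count
    measured = rng.random((S, L)) >= spec.missingness

    sample_col = np.repeat(samples, L)
    truth = pd.DataFrame(
        {
            "sample_id": sample_col,
            "variant_id": np.tile(loci["variant_id"].to_numpy(), S),
            "contig": np.tile(loci["contig"].to_numpy(), S),
            "position": np.tile(loci["position"].to_numpy(), S),
            "zygosity": np.where(is_hom.ravel(), ZYGOSITY_HOM, ZYGOSITY_HET),
            "true_p_major": np.where(
                is_hom.ravel(), 1.0 - spec.hom_error_rate, p_major.ravel()
            ),
            "planted": np.tile(planted_loci, S),
            "measured": measured.ravel(),
        }
    )

    counts = pd.DataFrame(
        {
            "sample_id": sample_col,
            "contig": np.tile(loci["contig"].to_numpy(), S),
            "position": np.tile(loci["position"].to_numpy(), S),
            "variant_id": np.tile(loci["variant_id"].to_numpy(), S),
            "ref_allele": np.tile(loci["ref_allele"].to_numpy(), S),
            "alt_allele": np.tile(loci["alt_allele"].to_numpy(), S),
            "ref_count": ref_count.ravel(),
            "alt_count": alt_count.ravel(),
        }
    ).loc[measured.ravel()].reset_index(drop=True)

    n_genotyped = int(round(spec.genotyped_fraction * S))
    genotyped_samples = samples[:n_genotyped]
    geno_mask = np.isin(truth["sample_id"].to_numpy(), genotyped_samples)
    genotypes = truth.loc[
        geno_mask, ["sample_id", "contig", "position", "zygosity"]
    ].reset_index(drop=True)

    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "group_label": [groups[s] for s in samples],
            "genotyped": [s in set(genotyped_samples) for s in samples],
        }
    )

    gene_idx = loci["locus"] // spec.snps_per_gene
    snp_gene_map = pd.DataFrame(
        {
            "variant_id": loci["variant_id"],
            "gene_id": [f"ENSG{g:08d}" for g in gene_idx],
            "gene_symbol": [f"GENE{g}" for g in gene_idx],
        }
    )

    cohort = SyntheticCohort(
        spec=spec,
        counts=counts,
        genotypes=genotypes,
        metadata=metadata,
        truth=truth,
        snp_gene_map=snp_gene_map,
    )
    # stash per-sample hom-ref/hom-alt detail needed only for VCF writing
    hom_ref = np.where(is_hom & ref_is_major, "0/0", "1/1")
    gt = np.where(is_hom, hom_ref, "0/1")
    cohort._gt_matrix = pd.DataFrame(  # type: ignore[attr-defined]
        gt[:n_genotyped].T, columns=genotyped_samples
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort to disk in the pipeline's input formats.

    Layout: ``counts/<sample>.tsv`` (ASEReadCounter dialect),
    ``genotypes.vcf`` (truthful multi-sample VCF for genotyped samples),
    ``metadata.tsv``, ``truth.tsv``, ``snp_gene_map.tsv``.
    """
    out_dir = Path(out_dir)
    counts_dir = out_dir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec

    dialect = cohort.counts.rename(
        columns={
            "variant_id": "variantID",
            "ref_allele": "refAllele",
            "alt_allele": "altAllele",
            "ref_count": "refCount",
            "alt_count": "altCount",
        }
    )
    dialect["totalCount"] = dialect["refCount"] + dialect["altCount"]
    file_cols = [
        "contig", "position", "variantID", "refAllele", "altAllele",
        "refCount", "altCount", "totalCount",
    ]
    for sid in spec.sample_ids:
        sub = dialect.loc[dialect["sample_id"] == sid, file_cols]
        sub.to_csv(counts_dir / f"{sid}.tsv", sep="\t", index=False)

    cohort.metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    cohort.snp_gene_map.to_csv(out_dir / "snp_gene_map.tsv", sep="\t", index=False)

    gt_matrix: pd.DataFrame = cohort._gt_matrix  # type: ignore[attr-defined]
    if gt_matrix.shape[1] > 0:
        _write_vcf(cohort, gt_matrix, out_dir / "genotypes.vcf")


def _write_vcf(cohort: SyntheticCohort, gt_matrix: pd.DataFrame, path: Path) -> None:
    spec = cohort.spec
    loci = _locus_table(spec)
    samples = list(gt_matrix.columns)
    lines = ["##fileformat=VCFv4.2", "##source=aseflow-simulate"]
    for contig in loci["contig"].unique():
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for i, row in loci.iterrows():
        gts = "\t".join(gt_matrix.iloc[i])
        lines.append(
            f"{row['contig']}\t{row['position']}\t{row['variant_id']}\t"
            f"{row['ref_allele']}\t{row['alt_allele']}\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def planted_locus_recovery(
    truth: pd.DataFrame,
    tested: pd.DataFrame,
    q_cutoff: float = 0.05,
    min_samples: int = 2,
) -> tuple[float, float]:
    """Locus-level sensitivity and false-discovery proportion.

    A locus is *discovered* when it is significantly imbalanced
    (q < ``q_cutoff``) in at least ``min_samples`` samples; requiring
    more than one sample guards against isolated homozygosity-leak
    artifacts. Returns (sensitivity over planted loci, FDP among
    discovered loci).
    """
    sig = tested.loc[tested["q_value"] < q_cutoff]
    per_locus = sig.groupby("variant_id")["sample_id"].nunique()
    discovered = set(per_locus[per_locus >= min_samples].index)
    planted = set(truth.loc[truth["planted"], "variant_id"])
    if not planted:
        sensitivity = float("nan")
    else:
        sensitivity = len(discovered & planted) / len(planted)
    fdp = len(discovered - planted) / len(discovered) if discovered else 0.0
    return sensitivity, fdp
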
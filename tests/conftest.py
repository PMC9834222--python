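import numpy as np
import pytest

from aseflow import ase_core, synthetic


def folded_binomial_scores(rng, n_draws, depth, p):
    """Folded ASE scores of Binomial(depth, p) reference counts."""
    k = rng.binomial(depth, p, size=n_draws)
    return np.abs(k / depth - 0.5) + 0.5


@pytest.fixture(scope="session")
def small_cohort():
    """12-sample cohort with 10 strongly imbalanced loci, on-disk copy included."""
    spec = synthetic.CohortSpec(
        n_samples=12,
        n_loci=300,
        seed=11,
        imbalanced_loci={i * 25 + 1: 0.9 for i in range(10)},
    )
    return synthetic.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    synthetic.write_cohort(small_cohort, out)
    return out


@pytest.fixture(scope="session")
def tested_small_cohort(small_cohort):
    """The small cohort pushed through score -> filter -> test."""
    from aseflow import stats

    scored = ase_core.score_records(small_cohort.counts)
    classified = ase_core.classify_and_filter(
        scored, small_cohort.genotypes, threshold=0.9
    )
    retained = ase_core.filter_retained(classified)
    tested, null = stats.test_records(retained)
    return tested, null


def write_vcf(path, records, samples):
    """Write a minimal VCF: records are (chrom, pos, id, ref, alt, [gt...])."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    contigs = sorted({r[0] for r in records})
    for c in contigs:
        lines.insert(1, f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, vid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
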
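"""Readers and writers for every external table the pipeline touches.

All tabular data moves through pandas DataFrames with fixed column
contracts; readers validate schemas eagerly and report row-level parse
problems with 1-based file line numbers.

Column contracts
----------------
allele counts   : sample_id, contig, position, variant_id, ref_allele,
                  alt_allele, ref_count, alt_count
genotype calls  : sample_id, contig, position, zygosity
                  (zygosity in {"heterozygous", "homozygous"})
sample metadata : sample_id, group_label, genotyped
SNP-gene map    : variant_id, gene_id, gene_symbol
edge list       : protein_a, protein_b, confidence
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# ASEReadCounter column names -> internal names. Extra columns ignored.
_COUNT_COLUMN_MAP = {
    "contig": "contig",
    "position": "position",
    "variantID": "variant_id",
    "refAllele": "ref_allele",
    "altAllele": "alt_allele",
    "refCount": "ref_count",
    "altCount": "alt_count",
}
_MANDATORY_COUNT_COLUMNS = ("contig", "position", "variantID", "refCount", "altCount")

COUNT_COLUMNS = [
    "sample_id",
    "contig",
    "position",
    "variant_id",
    "ref_allele",
    "alt_allele",
    "ref_count",
    "alt_count",
]

ZYGOSITY_HET = "heterozygous"
ZYGOSITY_HOM = "homozygous"


class FormatError(ValueError):
    """A file violates its schema (missing column, duplicate key, ...)."""


class RowParseError(FormatError):
    """One or more data rows could not be parsed.

    Carries the 1-based line numbers of the offending rows.
    """

    def __init__(self, path, lines: Sequence[int], message: str):
        self.path = str(path)
        self.lines = list(lines)
        shown = ", ".join(str(x) for x in self.lines[:10])
        super().__init__(f"{path}: {message} (line(s) {shown})")


def _bad_lines(mask: pd.Series) -> list[int]:
    # +2: header is line 1, first data row is line 2
    return [int(i) + 2 for i in mask[mask].index]


def read_allele_counts(
    path, min_depth: int = 10, sample_id: str | None = None
) -> pd.DataFrame:
    """Read one sample's allele count table (ASEReadCounter dialect).

    Parameters
    ----------
    path
        Tab-separated file with a header naming at least
        ``contig, position, variantID, refCount, altCount``; column order
        is irrelevant and extra columns (e.g. ``totalCount``) are ignored.
    min_depth
        Keep loci with ``ref_count + alt_count >= min_depth``; use 1 for
        no filtering. Filtered rows are counted and logged, not returned.
    sample_id
        Sample label attached to every row; defaults to the file stem
        (with a trailing ``.counts`` stripped).

    Returns
    -------
    DataFrame with the allele-count column contract. ``attrs`` carries
    ``n_parsed`` and ``n_below_depth`` for audit.
    """
    path = Path(path)
    if min_depth < 1:
        raise ValueError(f"min_depth must be >= 1, got {min_depth}")
    if sample_id is None:
        sample_id = path.stem
        if sample_id.endswith(".counts"):
            sample_id = sample_id[: -len(".counts")]
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (no header)") from None

    missing = [c for c in _MANDATORY_COUNT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    present = {src: dst for src, dst in _COUNT_COLUMN_MAP.items() if src in raw.columns}
    df = raw[list(present)].rename(columns=present)
    for col in ("ref_allele", "alt_allele"):
        if col not in df.columns:
            df[col] = "."

    for col, what in (("position", "position"), ("ref_count", "refCount"),
                      ("alt_count", "altCount")):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            raise RowParseError(path, _bad_lines(bad), f"non-integer {what}")
        df[col] = converted.astype(int)

    if (df["position"] < 1).any():
        raise RowParseError(path, _bad_lines(df["position"] < 1), "position < 1")
    neg = (df["ref_count"] < 0) | (df["alt_count"] < 0)
    if neg.any():
        raise RowParseError(path, _bad_lines(neg), "negative read count")
    typed = df["ref_allele"].ne(".") & df["alt_allele"].ne(".")
    same = typed & df["ref_allele"].eq(df["alt_allele"])
    if same.any():
        raise RowParseError(path, _bad_lines(same), "refAllele == altAllele")

    dup = df.duplicated(subset=["contig", "position"], keep=False)
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (contig, position) rows at line(s) "
            f"{', '.join(str(x) for x in _bad_lines(dup)[:10])}"
        )

    depth = df["ref_count"] + df["alt_count"]
    kept = df.loc[depth >= min_depth].copy()
    n_filtered = len(df) - len(kept)
    if n_filtered:
        logger.info(
            "%s: %d/%d loci below min_depth=%d removed",
            path.name, n_filtered, len(df), min_depth,
        )
    kept.insert(0, "sample_id", sample_id)
    kept = kept[COUNT_COLUMNS].reset_index(drop=True)
    kept.attrs["n_parsed"] = len(df)
    kept.attrs["n_below_depth"] = n_filtered
    return kept


def read_cohort_counts(source, min_depth: int = 10) -> pd.DataFrame:
    """Read allele counts for a whole cohort.

    ``source`` is a directory (all ``*.tsv`` files, one per sample, sample
    id taken from the file name) or an iterable of file paths.
    """
    source_path = Path(source) if isinstance(source, (str, Path)) else None
    if source_path is not None and source_path.is_dir():
        paths = sorted(source_path.glob("*.tsv"))
        if not paths:
            raise FormatError(f"{source_path}: no *.tsv count files found")
    elif source_path is not None:
        paths = [source_path]
    else:
        paths = [Path(p) for p in source]
    frames = [read_allele_counts(p, min_depth=min_depth) for p in paths]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COUNT_COLUMNS)
    out.attrs["n_parsed"] = sum(f.attrs.get("n_parsed", len(f)) for f in frames)
    out.attrs["n_below_depth"] = sum(f.attrs.get("n_below_depth", 0) for f in frames)
    dup = out.duplicated(subset=["sample_id", "contig", "position"], keep=False)
    if dup.any():
        raise FormatError("duplicate (sample_id, contig, position) across count files")
    return out


def read_genotypes(path, samples: Iterable[str]) -> pd.DataFrame:
    """Extract zygosity calls for the requested samples from a VCF.

    One call per biallelic SNP x sample with a called diploid genotype:
    0/1 and 1/0 (phased or not) are heterozygous, 0/0 and 1/1 homozygous.
    Missing genotypes are skipped; multi-allelic and non-SNP records are
    skipped with a logged count.
    """
    from cyvcf2 import VCF

    samples = sorted(set(samples))
    vcf = VCF(str(path), gts012=True)
    missing = sorted(set(samples) - set(vcf.samples))
    if missing:
        raise FormatError(
            f"{path}: sample(s) not in VCF header: {', '.join(missing)}"
        )
    vcf = VCF(str(path), gts012=True, samples=samples)
    order = list(vcf.samples)

    rows: list[tuple[str, str, int, str]] = []
    n_skipped = 0
    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
        ):
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        for sid, gt in zip(order, variant.gt_types):
            if gt == 1:
                rows.append((sid, variant.CHROM, variant.POS, ZYGOSITY_HET))
            elif gt in (0, 2):
                rows.append((sid, variant.CHROM, variant.POS, ZYGOSITY_HOM))
    if n_skipped:
        logger.info("%s: skipped %d multi-allelic/non-SNP records", path, n_skipped)
    out = pd.DataFrame(rows, columns=["sample_id", "contig", "position", "zygosity"])
    out.attrs["n_multiallelic_skipped"] = n_skipped
    return out


def vcf_samples(path) -> list[str]:
    """Sample names declared in a VCF header."""
    from cyvcf2 import VCF

    return list(VCF(str(path)).samples)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample-to-group table (sample_id, group_label[, genotyped])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group_label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample_id(s): {', '.join(dups[:10])}")
    if "genotyped" in df.columns:
        df["genotyped"] = df["genotyped"].str.lower().isin(("true", "1", "yes"))
    else:
        df["genotyped"] = False
    return df[["sample_id", "group_label", "genotyped"]]


def read_snp_gene_map(path) -> pd.DataFrame:
    """Read the SNP-to-gene annotation (variant_id, gene_id[, gene_symbol]).

    A variant may map to several genes; duplicate (variant_id, gene_id)
    pairs are collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = df["gene_id"]
    df = df[["variant_id", "gene_id", "gene_symbol"]].drop_duplicates(
        subset=["variant_id", "gene_id"]
    )
    return df.reset_index(drop=True)


def read_gene_set(path) -> set[str]:
    """Read a plain gene list: one identifier per line, '#' comments allowed."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            genes.add(token.split("\t")[0])
    return genes


def read_edge_list(path) -> pd.DataFrame:
    """Read a protein-protein edge list (protein_a, protein_b, confidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_a", "protein_b", "confidence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad = conf.isna() | (conf < 0) | (conf > 1)
    if bad.any():
        raise RowParseError(path, _bad_lines(bad), "confidence not a number in [0, 1]")
    df["confidence"] = conf
    return df[["protein_a", "protein_b", "confidence"]]


def write_results_table(rows, path) -> None:
    """Write any pipeline output table as headered TSV.

    Accepts a DataFrame or a sequence of mappings with a uniform schema.
    Floats are rendered with pandas' shortest round-trip representation,
    so ``read_results_table(write(...))`` reproduces values exactly.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            keys = list(rows[0].keys())
            for i, r in enumerate(rows[1:], start=1):
                if list(r.keys()) != keys:
                    raise FormatError(
                        f"row {i} schema {sorted(r.keys())} differs from row 0 "
                        f"schema {sorted(keys)}"
                    )
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def write_gene_list(genes: Iterable[str], path) -> None:
    """Write a plain one-per-line gene list (sorted) for external GO tools."""
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))
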
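"""Result views: density, QQ, Manhattan, per-group boxplots, PPI networks.

Every figure writes a sidecar TSV with the exact numbers plotted, so
downstream checks (and tests) run on tables, never on rendered pixels.
Re-running a plot on identical inputs yields byte-identical sidecars.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from aseflow import io_formats, stats

logger = logging.getLogger(__name__)

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))
DENSITY_BANDWIDTH_FLOOR = 1e-3


@dataclass
class NetworkSummary:
    """Filtered PPI network annotated with per-group median ASE scores."""

    nodes: pd.DataFrame      # node, group, median_ase, n_samples
    edges: pd.DataFrame      # protein_a, protein_b, confidence
    subgraphs: list[list[str]]  # connected components, largest first


def _sidecar(out) -> Path:
    return Path(out).with_suffix(".tsv")


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    h = 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
    return max(h, DENSITY_BANDWIDTH_FLOOR)


def kde_density(values, grid, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian kernel density on a fixed grid (Silverman bandwidth, floored).

    The bandwidth floor keeps single-value (degenerate) classes finite.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate a density from an empty class")
    h = _silverman_bandwidth(values) if bandwidth is None else bandwidth
    out = np.zeros_like(grid)
    for start in range(0, values.size, 10000):  # bound memory on big cohorts
        chunk = values[start : start + 10000]
        z = (grid[:, None] - chunk[None, :]) / h
        out += np.exp(-0.5 * z * z).sum(axis=1)
    return out / (values.size * h * _SQRT_2PI)


def plot_density_by_zygosity(
    scores, labels, threshold: float, out, n_grid: int = 512
) -> pd.DataFrame:
    """Score densities for het vs hom calibration loci, threshold marked.

    Returns (and writes as sidecar) the evaluated grid table with columns
    ``ase_score``, ``density_het``, ``density_hom``.
    """
    from aseflow.ase_core import _as_hom_mask

    scores = np.asarray(scores, dtype=float)
    is_hom = _as_hom_mask(labels)
    if not is_hom.any() or is_hom.all():
        raise ValueError("both zygosity classes must be non-empty")
    grid = np.linspace(0.5, 1.0, n_grid)
    table = pd.DataFrame(
        {
            "ase_score": grid,
            "density_het": kde_density(scores[~is_hom], grid),
            "density_hom": kde_density(scores[is_hom], grid),
        }
    )
    io_formats.write_results_table(table, _sidecar(out))

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, table["density_het"], label=f"heterozygous (n={int((~is_hom).sum())})")
    ax.plot(grid, table["density_hom"], label=f"homozygous (n={int(is_hom.sum())})")
    ax.axvline(threshold, linestyle=":", color="black",
               label=f"threshold = {threshold:.3f}")
    ax.set_xlabel("ASE score")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return table


def plot_qq(p_subset, p_rest, out) -> tuple[pd.DataFrame, dict[str, float]]:
    """QQ plot of -log10 p for a gene-subset's SNPs vs the rest."""
    table, lambdas = stats.qq_inflation(p_subset, p_rest)
    io_formats.write_results_table(table, _sidecar(out))
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, marker in (("subset", "o"), ("rest", ".")):
        sub = table.loc[table["membership"] == name]
        ax.scatter(
            sub["expected_neglog10"], sub["observed_neglog10"],
            s=8, marker=marker,
            label=f"{name} (lambda={lambdas[name]:.2f})",
        )
    lim = float(table[["expected_neglog10", "observed_neglog10"]].max().max())
    ax.plot([0, lim], [0, lim], color="grey", linewidth=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return table, lambdas


def natural_contig_key(contig) -> tuple:
    """Sort key placing contigs in 1..22, X, Y, MT order, others last."""
    s = re.sub("^chr", "", str(contig))
    if s.isdigit():
        return (0, int(s), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if s in special:
        return (0, special[s], "")
    return (1, 0, s)


def plot_manhattan(
    group_results: pd.DataFrame,
    out,
    significance: float = 0.05,
    value_col: str = "omnibus_q",
    top_n: int = 5,
) -> pd.DataFrame:
    """Manhattan plot of -log10 group-difference values by genomic order.

    Contigs are natural-sorted (1..22, X, Y, MT) with alternating
    shading; the ``top_n`` smallest values are labeled with
    ``gene_symbol`` when present, else ``variant_id``. Untestable SNPs
    (NaN) are omitted from the plot but kept in the sidecar.
    """
    for col in ("contig", "position", value_col):
        if col not in group_results.columns:
            raise ValueError(f"group results table lacks column {col!r}")
    table = group_results.copy()
    table["_key"] = table["contig"].map(natural_contig_key)
    table = table.sort_values(["_key", "position"], kind="mergesort").drop(columns="_key")
    offsets: dict = {}
    running = 0
    for contig in table["contig"].unique():
        offsets[contig] = running
        running += int(table.loc[table["contig"] == contig, "position"].max()) + 1
    table["cumulative_position"] = (
        table["contig"].map(offsets) + table["position"]
    )
    with np.errstate(divide="ignore"):
        table["neglog10"] = -np.log10(table[value_col])
    table["significant"] = table[value_col] < significance
    finite = table.loc[np.isfinite(table["neglog10"])]
    labeled = set(
        finite.nsmallest(top_n, value_col)["variant_id"]
    ) if len(finite) else set()
    table["labeled"] = table["variant_id"].isin(labeled)
    table = table.reset_index(drop=True)
    finite = table.loc[np.isfinite(table["neglog10"])]
    io_formats.write_results_table(table, _sidecar(out))

    fig, ax = plt.subplots(figsize=(9, 4))
    for i, contig in enumerate(table["contig"].unique()):
        sub = finite.loc[finite["contig"] == contig]
        ax.scatter(
            sub["cumulative_position"], sub["neglog10"], s=6,
            color="steelblue" if i % 2 == 0 else "lightsteelblue",
        )
    ax.axhline(-np.log10(significance), color="red", linewidth=1, linestyle="--")
    name_col = "gene_symbol" if "gene_symbol" in table.columns else "variant_id"
    for _, row in finite.loc[finite["labeled"]].iterrows():
        ax.annotate(
            str(row[name_col]), (row["cumulative_position"], row["neglog10"]),
            fontsize=7, textcoords="offset points", xytext=(2, 2),
        )
    ax.set_xlabel("genomic position")
    ax.set_ylabel(f"-log10 {value_col}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return table


def plot_group_boxplot(variant_id: str, scores_by_group, out) -> pd.DataFrame:
    """Per-group ASE score distribution for one SNP, with group sizes.

    Sidecar columns: group, n, minimum, q1, median, q3, maximum (NaN
    rows for empty groups).
    """
    rows = []
    for group in sorted(scores_by_group):
        values = np.asarray(scores_by_group[group], dtype=float)
        if values.size:
            q0, q1, q2, q3, q4 = np.percentile(values, [0, 25, 50, 75, 100])
        else:
            q0 = q1 = q2 = q3 = q4 = float("nan")
        rows.append(
            {
                "group": group, "n": int(values.size),
                "minimum": q0, "q1": q1, "median": q2, "q3": q3, "maximum": q4,
            }
        )
    table = pd.DataFrame(rows)
    io_formats.write_results_table(table, _sidecar(out))

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = []
    data = []
    for _, row in table.iterrows():
        labels.append(f"{row['group']}\n(n={row['n']})")
        values = np.asarray(scores_by_group[row["group"]], dtype=float)
        data.append(values if values.size else np.array([np.nan]))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("ASE score")
    ax.set_title(variant_id)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return table


def build_network_summary(
    gene_rows: pd.DataFrame,
    edges: pd.DataFrame,
    cutoff: float = 0.9,
    metadata: pd.DataFrame | None = None,
    out=None,
    node_key: str = "gene_symbol",
    max_figures: int = 10,
) -> NetworkSummary:
    """Build the filtered interaction network over measured genes.

    Edges below ``cutoff`` confidence are dropped, nodes are restricted
    to genes present in ``gene_rows`` (isolated genes excluded), and per
    node and patient group the median representative-SNP ASE score is
    computed. Connected components are emitted largest first; with
    ``out`` set, sidecar tables (``*_nodes.tsv``, ``*_edges.tsv``,
    ``*_components.tsv``) and one figure per component (up to
    ``max_figures``) are written.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    present = set(gene_rows[node_key])
    kept = edges.loc[
        (edges["confidence"] >= cutoff)
        & edges["protein_a"].isin(present)
        & edges["protein_b"].isin(present)
        & (edges["protein_a"] != edges["protein_b"])
    ].reset_index(drop=True)
    graph = nx.Graph()
    graph.add_weighted_edges_from(
        kept[["protein_a", "protein_b", "confidence"]].itertuples(index=False),
        weight="confidence",
    )
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c),
    )

    annotated = gene_rows
    if metadata is not None:
        annotated = gene_rows.merge(
            metadata[["sample_id", "group_label"]], on="sample_id", how="inner"
        )
    else:
        annotated = annotated.assign(group_label="all")
    in_graph = annotated.loc[annotated[node_key].isin(graph.nodes)]
    nodes = (
        in_graph.groupby([node_key, "group_label"])
        .agg(median_ase=("best_ase_score", "median"), n_samples=("sample_id", "nunique"))
        .reset_index()
        .rename(columns={node_key: "node", "group_label": "group"})
        .sort_values(["node", "group"], kind="mergesort")
        .reset_index(drop=True)
    )
    summary = NetworkSummary(nodes=nodes, edges=kept, subgraphs=components)
    logger.info(
        "network: %d nodes, %d edges (confidence >= %.2f), %d component(s)",
        graph.number_of_nodes(), graph.number_of_edges(), cutoff, len(components),
    )

    if out is not None:
        out = Path(out)
        stem = out.with_suffix("")
        io_formats.write_results_table(nodes, Path(f"{stem}_nodes.tsv"))
        io_formats.write_results_table(kept, Path(f"{stem}_edges.tsv"))
        comp_table = pd.DataFrame(
            {
                "component": [i for i, c in enumerate(components) for _ in c],
                "node": [n for c in components for n in c],
            }
        )
        io_formats.write_results_table(comp_table, Path(f"{stem}_components.tsv"))
        overall = nodes.groupby("node")["median_ase"].median()
        for i, comp in enumerate(components[:max_figures]):
            sub = graph.subgraph(comp)
            fig, ax = plt.subplots(figsize=(5, 5))
            pos = nx.spring_layout(sub, seed=0)
            colors = [overall.get(n, np.nan) for n in sub.nodes]
            nx.draw_networkx(
                sub, pos=pos, ax=ax, node_color=colors, cmap="viridis",
                vmin=0.5, vmax=1.0, node_size=300, font_size=7,
            )
            ax.set_axis_off()
            fig.tight_layout()
            fig.savefig(f"{stem}_component{i}{out.suffix or '.png'}", dpi=150)
            plt.close(fig)
    return summary
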
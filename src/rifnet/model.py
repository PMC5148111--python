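"""Model/Results facade over the full regulator-discovery pipeline.

``RegulatorDiscovery`` holds a dataset, a regulator list and the analysis
parameters; ``fit()`` runs preprocessing, the per-probe factorial ANOVA,
PIF, PCIT edge filtering in both high-altitude groups, RIF scoring and
network extraction, and returns a ``RegulatorDiscoveryResults`` object
carrying every intermediate table plus ``summary()`` and ``save()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import anova, io, pcit, pif, preprocess, rif
from .network import extract_network, network_stats

__all__ = ["RegulatorDiscovery", "RegulatorDiscoveryResults"]


class RegulatorDiscovery:
    """Differential co-expression regulator discovery on a 2×2 design.

    Parameters
    ----------
    dataset : rifnet.io.Dataset
        Expression, flags and the breed × altitude design.
    tr_genes : sequence of str
        Transcriptional-regulator gene symbols (matched through the
        dataset's probe annotation).
    alpha : float
        FDR threshold for the DEG and differential-PIF selections
        (default 1e-4).
    r_min : float
        Hard |r| threshold on PCIT-significant edges (default 0.95).
    top_k : int
        Extreme regulators per sign per RIF criterion used to seed the
        networks (default 5).
    z_cut : float
        |z| threshold counted in the summary (default 2).
    group1, group2 : str
        The contrasted cells for PIF/PCIT/RIF, default the two breeds at
        high altitude ("TH" vs "DH").
    assume_log2 : bool
        Whether the expression matrix is already on the log2 scale
        (default True; raw-scale input is quantile-normalized then
        log2-transformed).
    """

    def __init__(
        self,
        dataset: io.Dataset,
        tr_genes,
        *,
        alpha: float = 1e-4,
        r_min: float = 0.95,
        top_k: int = 5,
        z_cut: float = 2.0,
        group1: str = "TH",
        group2: str = "DH",
        assume_log2: bool = True,
    ) -> None:
        self.dataset = dataset
        self.tr_genes = list(tr_genes)
        self.alpha = alpha
        self.r_min = r_min
        self.top_k = top_k
        self.z_cut = z_cut
        self.group1 = group1
        self.group2 = group2
        self.assume_log2 = assume_log2

    @classmethod
    def from_files(
        cls,
        expression_path,
        design_path,
        tr_list_path,
        flags_path=None,
        annotation_path=None,
        **kwargs,
    ) -> "RegulatorDiscovery":
        dataset = io.read_dataset(expression_path, design_path, flags_path, annotation_path)
        return cls(dataset, io.read_tr_list(tr_list_path), **kwargs)

    def params(self) -> dict:
        return {
            "alpha": self.alpha,
            "r_min": self.r_min,
            "top_k": self.top_k,
            "z_cut": self.z_cut,
            "group1": self.group1,
            "group2": self.group2,
            "assume_log2": self.assume_log2,
            "n_tr_genes": len(self.tr_genes),
        }

    # ------------------------------------------------------------------
    def fit(self) -> "RegulatorDiscoveryResults":
        ds = preprocess.filter_expressed(self.dataset)
        expr = preprocess.normalize(ds.expression, assume_log2=self.assume_log2)
        design = ds.design
        annot = ds.probe_annotation

        anova_table = anova.add_fdr(anova.two_way_anova(expr, design))
        deg_probes, deg_genes = anova.select_degs(anova_table, self.alpha, annot)
        pif_table = pif.compute_pif(expr, design, self.group1, self.group2)
        _, pif_probes, pif_genes = pif.differential_pif(expr, design, self.alpha, annot)

        # gene-level collapse: one representative probe per DE gene
        if annot is not None:
            deg_repr = anova.collapse_probes(anova_table, deg_probes, annot)
            pif_repr = anova.collapse_probes(anova_table, pif_probes, annot)
            tr_probes = sorted(
                annot.index[annot.isin(self.tr_genes)].intersection(expr.index).astype(str)
            )
        else:
            deg_repr = {p: p for p in deg_probes}
            pif_repr = {p: p for p in pif_probes}
            tr_probes = sorted(set(self.tr_genes) & set(expr.index.astype(str)))

        de_repr_probes = sorted(deg_repr.values())
        pif_repr_probes = sorted(pif_repr.values())
        universe = sorted(set(de_repr_probes) | set(pif_repr_probes) | set(tr_probes))

        edges, masks = {}, {}
        for grp in (self.group1, self.group2):
            samples = io.group_samples(design, grp)
            corr = pcit.correlation_matrix(expr.loc[universe], samples)
            mask = pcit.pcit_filter(corr)
            edges[grp] = pcit.threshold_edges(corr, mask, self.r_min, group=str(grp))
            masks[grp] = mask

        rif_table = rif.score_regulators(
            expr, design, tr_probes, de_repr_probes, self.group1, self.group2
        ) if tr_probes and de_repr_probes else pd.DataFrame(
            columns=["rif1", "rif2", "z1", "z2", "n_pairs", "scored"]
        )
        if annot is not None and len(rif_table):
            rif_table = rif_table.assign(gene=[annot.get(p, p) for p in rif_table.index])

        networks = {}
        if len(rif_table) and rif_table["scored"].any():
            for grp in (self.group1, self.group2):
                networks[grp] = extract_network(
                    edges[grp], rif_table,
                    degs=set(de_repr_probes), pif_set=set(pif_repr_probes),
                    k=self.top_k, criterion="both",
                )

        return RegulatorDiscoveryResults(
            model=self,
            filtered=ds,
            expression=expr,
            anova_table=anova_table,
            deg_probes=deg_probes,
            deg_genes=deg_genes,
            pif_table=pif_table,
            diff_pif_probes=pif_probes,
            diff_pif_genes=pif_genes,
            universe=universe,
            edges=edges,
            rif_table=rif_table,
            networks=networks,
        )


@dataclass
class RegulatorDiscoveryResults:
    """Everything one fitted run produced."""

    model: RegulatorDiscovery
    filtered: io.Dataset
    expression: pd.DataFrame
    anova_table: pd.DataFrame
    deg_probes: list[str]
    deg_genes: list[str]
    pif_table: pd.DataFrame
    diff_pif_probes: list[str]
    diff_pif_genes: list[str]
    universe: list[str]
    edges: dict[str, pd.DataFrame]
    rif_table: pd.DataFrame
    networks: dict[str, nx.Graph] = field(default_factory=dict)

    def network_summaries(self) -> dict[str, dict]:
        return {grp: network_stats(g) for grp, g in sorted(self.networks.items())}

    def summary(self) -> str:
        m = self.model
        lines = [
            "Regulator discovery summary",
            "===========================",
            f"probes after present-filter : {self.expression.shape[0]}",
            f"samples                     : {self.expression.shape[1]}",
            f"DEG probes (q<{m.alpha:g}, breed & interaction) : {len(self.deg_probes)}",
            f"DEG genes  (collapsed)      : {len(self.deg_genes)}",
            f"differential-PIF probes     : {len(self.diff_pif_probes)}",
            f"scored regulator probes     : {int(self.rif_table['scored'].sum()) if len(self.rif_table) else 0}",
        ]
        if len(self.rif_table):
            z1, z2 = self.rif_table["z1"], self.rif_table["z2"]
            lines += [
                f"RIF1 |z| > {m.z_cut:g}           : {int((z1.abs() > m.z_cut).sum())}",
                f"RIF2 |z| > {m.z_cut:g}           : {int((z2.abs() > m.z_cut).sum())}",
            ]
            for crit in ("rif1", "rif2"):
                pos, neg = rif.top_regulators(self.rif_table, crit, m.top_k)
                lines.append(f"top {m.top_k} positive {crit.upper()}       : {', '.join(pos) or '-'}")
                lines.append(f"top {m.top_k} negative {crit.upper()}       : {', '.join(neg) or '-'}")
        for grp, stats_ in self.network_summaries().items():
            lines.append(
                f"network {grp}: {stats_['n_nodes']} nodes, {stats_['n_edges']} edges, "
                f"{stats_['n_isolated']} unconnected regulators"
            )
        return "\n".join(lines)

    def save(self, out_dir, seed: int | None = None) -> dict[str, Path]:
        """Write every result table, the networks and run metadata.

        Output is deterministic: rerunning the same fit writes
        byte-identical files.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def save_tsv(name: str, df: pd.DataFrame, label: str = "probe") -> None:
            paths[name] = out / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index_label=label, float_format="%.10g")

        save_tsv("anova", self.anova_table)
        save_tsv("pif", self.pif_table)
        if len(self.rif_table):
            save_tsv("rif", self.rif_table.sort_values("z1", ascending=False))
        for name, items in (
            ("deg_probes", self.deg_probes),
            ("deg_genes", self.deg_genes),
            ("diff_pif_probes", self.diff_pif_probes),
            ("diff_pif_genes", self.diff_pif_genes),
        ):
            paths[name] = out / f"{name}.txt"
            paths[name].write_text("".join(f"{x}\n" for x in items))
        for grp, df in sorted(self.edges.items()):
            paths[f"edges_{grp}"] = out / f"edges_{grp}.tsv"
            df.to_csv(paths[f"edges_{grp}"], sep="\t", index=False, float_format="%.10g")
        for grp, g in sorted(self.networks.items()):
            for fmt in ("sif", "graphml"):
                key = f"network_{grp}_{fmt}"
                paths[key] = out / f"network_{grp}.{fmt}"
                io.write_network(g, paths[key], fmt)
        paths["network_stats"] = out / "network_stats.json"
        paths["network_stats"].write_text(
            json.dumps(self.network_summaries(), indent=2, sort_keys=True) + "\n"
        )
        paths["metadata"] = out / "run_metadata.json"
        paths["metadata"].write_text(
            json.dumps(io.run_metadata(seed, self.model.params()), indent=2, sort_keys=True) + "\n"
        )
        paths["summary"] = out / "summary.txt"
        paths["summary"].write_text(self.summary() + "\n")
        return paths
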
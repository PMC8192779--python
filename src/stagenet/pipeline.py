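"""End-to-end orchestration: simulate/ingest -> DE -> networks -> enrichment.

``run_all`` executes the whole analysis from a single config and writes
every artifact as TSV plus a machine-readable ``report.json`` index.  Each
stage is recorded in the report as ``ok`` or ``skipped`` with a reason;
a failure in one stage skips only the stages that depend on it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, de, enrichment, io, markers as markers_mod, network
from .simulate import SimConfig, generate_cohort, generate_gene_sets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (real files or a simulate block),
    thresholds and the output directory."""

    outdir: str = "stagenet_out"
    seed: int = 0
    # real inputs (all four required together); ignored when simulate=True
    expression: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    simulate: bool = True
    sim: SimConfig | None = None
    # analysis thresholds
    alpha: float = 0.01
    progression_rule: str = "methods"
    r_min: float = 0.8
    net_alpha: float = 0.01
    fdr: float = 0.05
    hub_quantile: float = 0.95
    target_lncRNA: str | None = None
    markers: tuple[str, ...] = markers_mod.DEFAULT_MARKERS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus the section status index."""

    sections: dict[str, dict[str, Any]] = field(default_factory=dict)
    objects: dict[str, Any] = field(default_factory=dict)

    def ok(self, name: str, **meta: Any) -> None:
        self.sections[name] = {"status": "ok", **meta}

    def skip(self, name: str, reason: str) -> None:
        self.sections[name] = {"status": "skipped", "reason": reason}
        logger.warning("section %s skipped: %s", name, reason)


def _write(df: pd.DataFrame, path: Path, **kw) -> str:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    return str(path)


def run_all(cfg: PipelineConfig) -> ReportBundle:
    """Run the full pipeline and write artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ReportBundle()

    # ------------------------------------------------------------------ input
    truth = None
    gsc = None
    if cfg.simulate:
        sim = cfg.sim if cfg.sim is not None else SimConfig(seed=cfg.seed)
        em, st, ann, truth = generate_cohort(sim)
        gsc = generate_gene_sets(truth, sim)
        io.write_expression(em, st, outdir / "expression.tsv",
                            outdir / "samples.tsv")
        io.write_annotation(ann, outdir / "annotation.tsv")
        io.write_gene_sets(gsc, outdir / "gene_sets.gmt")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        report.ok("input", mode="simulate", seed=sim.seed,
                  n_genes=int(em.shape[0]), n_samples=int(em.shape[1]))
        target = cfg.target_lncRNA or truth.attrs.get("key_lncRNA")
    else:
        em, st = io.read_expression(cfg.expression, cfg.metadata)
        ann = io.read_annotation(cfg.annotation)
        gsc = io.read_gene_sets(cfg.gmt) if cfg.gmt else None
        report.ok("input", mode="files", expression=cfg.expression)
        target = cfg.target_lncRNA
    report.objects.update(expression=em, samples=st, annotation=ann,
                          gene_sets=gsc, truth=truth)

    # ------------------------------------------------------------------ DE
    de_cfg = de.DEConfig(alpha=cfg.alpha, progression_rule=cfg.progression_rule)
    try:
        ct = de.run_contrasts(em, st)
        sig = de.classify_signatures(ct, ann, de_cfg)
    except Exception as exc:  # noqa: BLE001 - stage-level containment
        report.skip("contrasts", f"differential expression failed: {exc}")
        downstream = ["signatures", "stage_comparison", "enrichment",
                      "target_gene_sets", "marker_correlation"]
        downstream += [f"{kind}_{tag}" for tag in
                       ("pathogenic", "early", "advanced")
                       for kind in ("network", "powerlaw", "hubs")]
        for name in downstream:
            report.skip(name, "requires the contrast stage")
        _finalize(report, cfg, outdir)
        return report
    de.contrast_table_tsv(ct, outdir / "contrasts.tsv")
    for name, table in de.signature_tables(sig).items():
        _write(table, outdir / f"signature_{name}.tsv")
    report.ok("contrasts", n_genes=int(len(ct)))
    report.ok(
        "signatures",
        progression_rule=sig.progression_rule,
        counts={k: len(v) for k, v in
                [("deg1", sig.deg1), ("deg2", sig.deg2), ("deg3", sig.deg3),
                 ("pathogenic", sig.pathogenic),
                 ("progression", sig.progression),
                 ("all_three", sig.all_three), ("rebound", sig.rebound)]},
        biotype_split={k: sig.split_by_biotype(v) for k, v in
                       [("pathogenic", sig.pathogenic),
                        ("progression", sig.progression)]},
    )
    report.objects.update(contrasts=ct, signatures=sig)

    # ------------------------------------------------------------- networks
    biotype = ann["biotype"]
    nets: dict[str, network.CoexpressionNetwork] = {}
    plans = {
        "pathogenic": (sig.pathogenic, "ipf"),
        "early": (sig.progression, "early"),
        "advanced": (sig.progression, "advanced"),
    }
    for tag, (genes, stage) in plans.items():
        lnc = {g for g in genes if biotype.get(g) == "lncRNA"}
        mrna = {g for g in genes if biotype.get(g) == "mRNA"}
        samples = io.stage_samples(st, stage)
        if not lnc or not mrna:
            report.skip(f"network_{tag}", "no lncRNA/mRNA candidates in signature")
            report.skip(f"powerlaw_{tag}", "network unavailable")
            report.skip(f"hubs_{tag}", "network unavailable")
            continue
        try:
            net = network.build_network(
                em, lnc, mrna, samples, r_min=cfg.r_min,
                alpha=cfg.net_alpha, stage_tag=tag,
            )
        except Exception as exc:  # noqa: BLE001
            report.skip(f"network_{tag}", str(exc))
            report.skip(f"powerlaw_{tag}", "network unavailable")
            report.skip(f"hubs_{tag}", "network unavailable")
            continue
        nets[tag] = net
        io.write_network(net, outdir, annotation=ann, prefix=tag)
        report.ok(f"network_{tag}", n_edges=net.n_edges,
                  n_nodes=len(net.nodes), n_samples=net.n_samples)

        dt = network.degree_distribution(net)
        _write(dt, outdir / f"{tag}_degree_distribution.tsv")
        try:
            fit = network.fit_power_law(dt)
            report.ok(f"powerlaw_{tag}", **asdict(fit))
            report.objects[f"powerlaw_{tag}"] = fit
        except Exception as exc:  # noqa: BLE001
            report.skip(f"powerlaw_{tag}", str(exc))
        hubs = network.rank_hubs(net, quantile=cfg.hub_quantile)
        _write(hubs, outdir / f"{tag}_hubs.tsv")
        report.ok(f"hubs_{tag}",
                  hubs=hubs.loc[hubs["is_hub"], "gene_id"].tolist()[:20])
    report.objects["networks"] = nets

    if "early" in nets and "advanced" in nets:
        comp = network.compare_networks(nets["early"], nets["advanced"])
        comp_rows = pd.DataFrame(
            {
                "category": ["common", "early_specific", "advanced_specific"],
                "n_nodes": [len(comp.common_nodes), len(comp.a_specific_nodes),
                            len(comp.b_specific_nodes)],
                "n_edges": [len(comp.common_edges), len(comp.a_specific_edges),
                            len(comp.b_specific_edges)],
            }
        )
        _write(comp_rows, outdir / "stage_comparison.tsv")
        report.ok("stage_comparison",
                  common_nodes=len(comp.common_nodes),
                  common_edges=len(comp.common_edges))
        report.objects["stage_comparison"] = comp
    else:
        report.skip("stage_comparison", "early or advanced network unavailable")

    # ------------------------------------------------------------ enrichment
    universe = set(em.index)
    if gsc is None:
        report.skip("enrichment", "no gene-set collection provided")
    elif "pathogenic" not in nets or nets["pathogenic"].n_edges == 0:
        report.skip("enrichment", "pathogenic network empty")
    else:
        query = {g for g, role in nets["pathogenic"].nodes.items()
                 if role == "mRNA"}
        table = enrichment.enrich(query, universe, gsc, fdr=cfg.fdr,
                                  category="pathway")
        _write(table, outdir / "enrichment_pathway.tsv")
        report.ok("enrichment", n_tested=int(len(table)),
                  n_significant=int(table["significant"].sum()))
        report.objects["enrichment"] = table

    # ------------------------------------------- coverage + Sankey for target
    if gsc is None or target is None:
        report.skip("target_gene_sets", "no target lncRNA or collection")
    else:
        partners: set[str] = set()
        for tag in ("pathogenic", "early", "advanced"):
            if tag in nets:
                partners |= nets[tag].neighbors(target)
        if not partners:
            report.skip("target_gene_sets",
                        f"target {target} has no network partners")
        else:
            links = enrichment.sankey_links(partners, gsc, category="fibrosis")
            _write(links, outdir / "target_sankey_links.tsv")
            cov_rows = [enrichment.coverage(g, gsc, category="fibrosis")
                        for g in sorted(partners)]
            cov = pd.DataFrame(
                {"gene": [c.gene for c in cov_rows],
                 "n_containing": [c.n_containing for c in cov_rows],
                 "n_total": [c.n_total for c in cov_rows],
                 "fraction": [c.fraction for c in cov_rows]}
            )
            _write(cov, outdir / "target_coverage.tsv")
            report.ok("target_gene_sets", target=target,
                      n_partners=len(partners), n_links=int(len(links)))
            report.objects["target_coverage"] = cov

    # ------------------------------------------------------------- markers
    if target is None:
        report.skip("marker_correlation", "no target lncRNA configured")
    else:
        marker_ids: list[str] = list(cfg.markers)
        if (cfg.simulate and truth is not None
                and tuple(cfg.markers) == markers_mod.DEFAULT_MARKERS):
            # synthetic marker genes carry generated ids, not symbols
            marker_ids = truth.index[truth["class"] == "marker"].tolist()
        ipf_samples = io.stage_samples(st, "ipf")
        try:
            mk = markers_mod.correlate_with_markers(
                em, target, marker_ids, ipf_samples
            )
        except Exception as exc:  # noqa: BLE001
            report.skip("marker_correlation", str(exc))
        else:
            _write(mk, outdir / "marker_correlations.tsv")
            report.ok("marker_correlation", target=target, n_markers=int(len(mk)))
            report.objects["marker_correlations"] = mk

    _finalize(report, cfg, outdir)
    return report


def _finalize(report: ReportBundle, cfg: PipelineConfig, outdir: Path) -> None:
    cfg_echo = asdict(cfg)
    if cfg_echo.get("sim") is not None:
        cfg_echo["sim"] = asdict(cfg.sim)
    cfg_echo["markers"] = list(cfg.markers)
    index = {
        "version": __version__,
        "config": cfg_echo,
        "thresholds": {"alpha": cfg.alpha, "r_min": cfg.r_min,
                       "net_alpha": cfg.net_alpha, "fdr": cfg.fdr,
                       "progression_rule": cfg.progression_rule},
        "sections": report.sections,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
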
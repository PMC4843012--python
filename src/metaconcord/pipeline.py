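"""End-to-end experiment: simulate -> group -> DE -> concordance -> methylation.

``run_experiment`` reproduces the replication design on synthetic
cohorts: every cohort is grouped under both policies (TNM-only and
TNM-plus-recurrence), differential expression is run per cohort and
policy, and every cohort pair is scored for cross-cohort concordance
under each policy — the summary table mirrors the per-pair, per-policy
(overlap, score, p) layout. One cohort optionally carries the
promoter-methylation arm (DM loci -> DM genes -> methylation-expression
concordance) and, when gene sets are supplied, direction-split
enrichment. Everything is deterministic given the seed, and every
intermediate table is persisted with a parameter-echo comment block.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as mio
from .concordance import (
    concordance,
    methylation_expression_concordance,
    signed_list_from_differential,
)
from .datatypes import Policy
from .differential import call_dm_genes, nb_exact_de, wilcoxon_de
from .enrichment import enrich_updown
from .grouping import assignments_to_frame, group_samples
from .simulate import GeneratorConfig, generate_multi_cohort, write_cohort

log = logging.getLogger("metaconcord")

__all__ = ["RunConfig", "run_experiment", "load_run_config"]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_cohorts: int = 2
    shared_de_fraction: float = 0.9
    counts_cohort: int | None = None
    methylation_cohort: int | None = 0
    fdr_de: float = 0.2
    fdr_dm: float = 0.2
    pe: float = 0.5
    policies: tuple[str, ...] = ("tnm_only", "tnm_plus_recurrence")
    adjuvant_available: bool = True
    gmt_path: str | None = None
    out_dir: str | Path = "metaconcord_run"


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (generator: subsection nested)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    gen = GeneratorConfig(**raw.pop("generator", {}))
    if "policies" in raw:
        raw["policies"] = tuple(raw["policies"])
    return RunConfig(generator=gen, **raw)


def _echo(cfg: RunConfig) -> list[str]:
    d = asdict(cfg)
    gen = d.pop("generator")
    lines = [f"{k}={v}" for k, v in sorted(d.items())]
    lines += [f"generator.{k}={v}" for k, v in sorted(gen.items())]
    return lines


def run_experiment(cfg: RunConfig) -> pd.DataFrame:
    """Run the full synthetic replication experiment; return the summary.

    Summary columns: cohort_a, cohort_b, policy, n_deg_a, n_deg_b,
    k_shared, s_concordant, score_pct, p_binomial, log10_p.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = _echo(cfg)

    log.info("simulating %d cohorts (seed=%d)", cfg.n_cohorts, cfg.generator.seed)
    cohorts = generate_multi_cohort(
        cfg.generator,
        n_cohorts=cfg.n_cohorts,
        shared_de_fraction=cfg.shared_de_fraction,
        counts_cohort=cfg.counts_cohort,
        methylation_cohort=cfg.methylation_cohort,
    )
    for c in cohorts:
        write_cohort(c, out / c.name, echo)

    de_lists: dict[tuple[str, str], object] = {}
    de_counts: dict[tuple[str, str], int] = {}
    for c in cohorts:
        for policy in cfg.policies:
            assigns = group_samples(
                c.annotations, policy, adjuvant_available=cfg.adjuvant_available
            )
            gdf = assignments_to_frame(assigns)
            mio.write_table(gdf, out / c.name / f"groups_{policy}.tsv", echo)
            sizes = gdf["group"].value_counts().to_dict()
            log.info("%s/%s groups: %s", c.name, policy, sizes)
            if c.counts is not None and cfg.counts_cohort is not None:
                dt = nb_exact_de(c.counts, assigns, cfg.fdr_de)
            else:
                dt = wilcoxon_de(c.expression, assigns, cfg.fdr_de)
            mio.write_table(dt.table, out / c.name / f"de_{policy}.tsv", echo)
            lst = signed_list_from_differential(
                dt, cfg.fdr_de, f"{c.name}:{policy}"
            )
            de_lists[(c.name, policy)] = lst
            de_counts[(c.name, policy)] = len(lst)
            log.info(
                "%s/%s: %d significant DEGs (FDR<%.2f) of %d features",
                c.name,
                policy,
                len(lst),
                cfg.fdr_de,
                len(dt),
            )

    rows = []
    for ca, cb in itertools.combinations([c.name for c in cohorts], 2):
        for policy in cfg.policies:
            res = concordance(
                de_lists[(ca, policy)], de_lists[(cb, policy)], pe=cfg.pe
            )
            rows.append(
                {
                    "cohort_a": ca,
                    "cohort_b": cb,
                    "policy": policy,
                    "n_deg_a": de_counts[(ca, policy)],
                    "n_deg_b": de_counts[(cb, policy)],
                    "k_shared": res.k,
                    "s_concordant": res.s,
                    "score_pct": res.score,
                    "p_binomial": res.p_binomial,
                    "log10_p": res.log10_p,
                }
            )
    summary = pd.DataFrame(rows)
    mio.write_table(summary, out / "concordance_summary.tsv", echo)

    meth_cohort = (
        cohorts[cfg.methylation_cohort]
        if cfg.methylation_cohort is not None
        else None
    )
    if meth_cohort is not None and meth_cohort.methylation is not None:
        policy = (
            "tnm_plus_recurrence"
            if "tnm_plus_recurrence" in cfg.policies
            else cfg.policies[0]
        )
        assigns = group_samples(
            meth_cohort.annotations,
            policy,
            adjuvant_available=cfg.adjuvant_available,
        )
        dm = wilcoxon_de(meth_cohort.methylation, assigns, cfg.fdr_dm)
        mio.write_table(dm.table, out / meth_cohort.name / "dm_loci.tsv", echo)
        dm_genes = call_dm_genes(
            dm.significant(cfg.fdr_dm), meth_cohort.methylation, assigns
        )
        dm_genes_uni = dm_genes[dm_genes["call"] != "excluded_bidirectional"]
        mio.write_table(dm_genes, out / meth_cohort.name / "dm_genes.tsv", echo)
        de_list = de_lists[(meth_cohort.name, policy)]
        mrows = []
        for mode in ("hyper_vs_down", "hypo_vs_up"):
            res = methylation_expression_concordance(
                dm_genes_uni, de_list, mode, pe=cfg.pe
            )
            mrows.append({"mode": mode, **res.to_frame().iloc[0].to_dict()})
            log.info(
                "methylation %s: k=%d s=%d score=%s p=%s",
                mode,
                res.k,
                res.s,
                res.score_display,
                res.p_binomial,
            )
        mio.write_table(
            pd.DataFrame(mrows), out / "methylation_concordance.tsv", echo
        )

    if cfg.gmt_path:
        sets = mio.read_gmt(cfg.gmt_path)
        ref = cohorts[0]
        policy = cfg.policies[-1]
        assigns = group_samples(
            ref.annotations, policy, adjuvant_available=cfg.adjuvant_available
        )
        dt = wilcoxon_de(ref.expression, assigns, cfg.fdr_de)
        up, down = enrich_updown(
            dt, sets, ref.expression.feature_ids, cfg.fdr_de
        )
        mio.write_table(up, out / "enrichment_up.tsv", echo)
        mio.write_table(down, out / "enrichment_down.tsv", echo)

    log.info("summary written to %s", out / "concordance_summary.tsv")
    return summary
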
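"""Synthetic multi-cohort generator with ground truth.

The generator encodes the study premise: the *observed* TNM staging of a
tumour is a corrupted readout of its *true* metastasis status, because
micrometastases escape routine pathology with probability
``fn_staging_rate``; post-surgery recurrence is a second, imperfect
readout of true status (truly metastatic patients recur with probability
``p_recur_given_met``, damped by adjuvant treatment). Expression carries
a true two-group effect on a configurable set of DE genes; an optional
count cohort and an optional promoter-methylation arm (anti-correlated
with expression for coupled genes) exercise the other test paths.

Hidden truth (true metastasis status, true DE/DM features) is emitted in
separate truth tables so analysis code can never consume it by accident.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    MethylationMatrix,
    MStage,
    NStage,
    SampleRecord,
    YesNoUnknown,
)
from . import io as mio

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort",
           "generate_multi_cohort", "write_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a scaled-down gastric-cancer-like cohort: 150
    resected tumours, 80% truly metastatic (resection cohorts are
    metastasis-heavy), 2000 genes of which 200 carry a 0.6 log2-unit
    shift against unit-SD noise, 30% of true metastases hidden by
    staging (micrometastases), 10% of true non-metastases falsely staged
    N+, and recurrence tracking true status at 80% sensitivity with a 5%
    background rate.
    """

    n_genes: int = 2000
    n_de_genes: int = 200
    n_samples: int = 150
    prevalence_true_met: float = 0.8
    effect_size_log2: float = 0.6
    noise_sd_log2: float = 1.0
    fn_staging_rate: float = 0.3
    fp_staging_rate: float = 0.1
    p_recur_given_met: float = 0.8
    p_recur_given_nonmet: float = 0.05
    adjuvant_rate: float = 0.2
    adjuvant_recur_reduction: float = 0.5
    nb_dispersion: float = 0.1
    mean_library_size: int = 100_000
    meth_coupling_prob: float = 0.9
    meth_effect_beta: float = 0.2
    seed: int = 0
    # probability a correctly staged true metastasis is called M+ (vs N+M0)
    m_plus_rate: float = 0.2
    # size of the null CpG-locus pool accompanying the coupled loci
    n_null_loci: int = 1000
    # minority pool whose methylation moves WITH expression (weakens the
    # hypo/up arm the way real promoter data does)
    meth_codirectional_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.n_de_genes <= self.n_genes):
            raise ValueError("need 0 < n_de_genes <= n_genes")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        closed_open = {
            "fn_staging_rate": self.fn_staging_rate,
            "fp_staging_rate": self.fp_staging_rate,
            "p_recur_given_nonmet": self.p_recur_given_nonmet,
        }
        for name, v in closed_open.items():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 < self.prevalence_true_met < 1.0):
            raise ValueError("prevalence_true_met must lie in (0, 1)")
        if not (0.0 < self.p_recur_given_met <= 1.0):
            raise ValueError("p_recur_given_met must lie in (0, 1]")
        unit = {
            "adjuvant_rate": self.adjuvant_rate,
            "adjuvant_recur_reduction": self.adjuvant_recur_reduction,
            "meth_coupling_prob": self.meth_coupling_prob,
            "m_plus_rate": self.m_plus_rate,
            "meth_codirectional_prob": self.meth_codirectional_prob,
        }
        for name, v in unit.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size_log2 <= 0 or self.noise_sd_log2 <= 0:
            raise ValueError("effect and noise SDs must be positive")
        if not (0.0 < self.meth_effect_beta < 1.0):
            raise ValueError("meth_effect_beta must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")


@dataclass
class SyntheticCohort:
    name: str
    expression: ExpressionMatrix
    annotations: list[SampleRecord]
    truth_samples: pd.DataFrame  # sample_id, true_met
    truth_genes: pd.DataFrame  # gene_id, true_de, sign
    counts: ExpressionMatrix | None = None
    methylation: MethylationMatrix | None = None
    truth_loci: pd.DataFrame | None = None
    config: GeneratorConfig | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _draw_de_signs(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, int]:
    genes = _gene_ids(cfg.n_genes)
    idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    signs = rng.choice([-1, 1], size=cfg.n_de_genes)
    return {genes[i]: int(s) for i, s in zip(sorted(idx), signs)}


def generate_cohort(
    cfg: GeneratorConfig,
    *,
    name: str = "cohort0",
    de_signs: dict[str, int] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    with_counts: bool = False,
    with_methylation: bool = True,
) -> SyntheticCohort:
    """Generate one cohort.

    ``de_signs`` (gene_id -> +1 up / -1 down in true metastases) overrides
    the internally drawn DE set; used by :func:`generate_multi_cohort` to
    share DE genes across cohorts. ``seed`` overrides ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = _gene_ids(cfg.n_genes)
    samples = [f"{name}_s{i:04d}" for i in range(cfg.n_samples)]

    if de_signs is None:
        de_signs = _draw_de_signs(cfg, rng)
    unknown = set(de_signs) - set(genes)
    if unknown:
        raise ValueError(f"de_signs references unknown genes: {sorted(unknown)[:5]}")
    sign_vec = np.array([de_signs.get(g, 0) for g in genes], dtype=float)

    true_met = rng.random(cfg.n_samples) < cfg.prevalence_true_met

    baseline = rng.normal(7.5, 1.5, size=cfg.n_genes)
    expr = (
        baseline[:, None]
        + cfg.effect_size_log2 * sign_vec[:, None] * true_met[None, :]
        + rng.normal(0.0, cfg.noise_sd_log2, size=(cfg.n_genes, cfg.n_samples))
    )
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), "log2_intensity"
    )

    # observed staging: micrometastases hide with prob fn_staging_rate;
    # correctly staged metastases are M+ with prob m_plus_rate, else N+M0;
    # true non-metastases are falsely N+ with prob fp_staging_rate
    hidden = rng.random(cfg.n_samples) < cfg.fn_staging_rate
    called_mplus = rng.random(cfg.n_samples) < cfg.m_plus_rate
    false_nplus = rng.random(cfg.n_samples) < cfg.fp_staging_rate
    n_stage = np.empty(cfg.n_samples, dtype=object)
    m_stage = np.empty(cfg.n_samples, dtype=object)
    for i in range(cfg.n_samples):
        if true_met[i]:
            if hidden[i]:
                n_stage[i], m_stage[i] = NStage.N0, MStage.M0
            elif called_mplus[i]:
                n_stage[i], m_stage[i] = NStage.N_PLUS, MStage.M_PLUS
            else:
                n_stage[i], m_stage[i] = NStage.N_PLUS, MStage.M0
        else:
            n_stage[i] = NStage.N_PLUS if false_nplus[i] else NStage.N0
            m_stage[i] = MStage.M0

    adjuvant = rng.random(cfg.n_samples) < cfg.adjuvant_rate
    p_rec = np.where(
        true_met,
        cfg.p_recur_given_met
        * np.where(adjuvant, cfg.adjuvant_recur_reduction, 1.0),
        cfg.p_recur_given_nonmet,
    )
    recurrence = rng.random(cfg.n_samples) < p_rec
    follow_up = np.round(rng.uniform(12.0, 60.0, size=cfg.n_samples), 1)

    annotations = [
        SampleRecord(
            samples[i],
            n_stage[i],
            m_stage[i],
            YesNoUnknown.YES if recurrence[i] else YesNoUnknown.NO,
            YesNoUnknown.YES if adjuvant[i] else YesNoUnknown.NO,
            float(follow_up[i]),
        )
        for i in range(cfg.n_samples)
    ]

    truth_samples = pd.DataFrame(
        {"sample_id": samples, "true_met": true_met.astype(int)}
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": genes,
            "true_de": (sign_vec != 0).astype(int),
            "sign": np.where(sign_vec > 0, "up", np.where(sign_vec < 0, "down", "")),
        }
    )

    counts = None
    if with_counts:
        lib = rng.poisson(cfg.mean_library_size, size=cfg.n_samples).astype(float)
        frac = 2.0**expr
        frac = frac / frac.sum(axis=0, keepdims=True)
        mu = frac * lib[None, :]
        if cfg.nb_dispersion > 0:
            r = 1.0 / cfg.nb_dispersion
            p = r / (r + mu)
            cvals = rng.negative_binomial(r, p)
        else:
            cvals = rng.poisson(mu)
        counts = ExpressionMatrix(
            pd.DataFrame(cvals.astype(float), index=genes, columns=samples),
            "raw_count",
        )

    methylation = None
    truth_loci = None
    if with_methylation:
        de_genes = sorted(de_signs)
        coupled = rng.random(len(de_genes)) < cfg.meth_coupling_prob
        codirectional = rng.random(len(de_genes)) < cfg.meth_codirectional_prob
        rows, loci, locus_gene, dm_sign = [], [], [], []
        for j, g in enumerate(de_genes):
            if not coupled[j]:
                continue
            base = rng.uniform(0.25, 0.65)
            # anti-correlated by default: expression up -> promoter loses
            # methylation in true metastases (hypo), down -> gains (hyper)
            shift_dir = -de_signs[g] if not codirectional[j] else de_signs[g]
            shift = shift_dir * cfg.meth_effect_beta
            beta = base + shift * true_met + rng.normal(0.0, 0.05, cfg.n_samples)
            rows.append(np.clip(beta, 0.01, 0.99))
            loci.append(f"cg_{g}")
            locus_gene.append(g)
            dm_sign.append("hyper" if shift_dir > 0 else "hypo")
        for i in range(cfg.n_null_loci):
            base = rng.uniform(0.1, 0.9)
            beta = base + rng.normal(0.0, 0.05, cfg.n_samples)
            rows.append(np.clip(beta, 0.01, 0.99))
            loci.append(f"cgnull{i:05d}")
            locus_gene.append(f"nullgene{i:05d}")
            dm_sign.append("")
        betas = pd.DataFrame(np.asarray(rows), index=loci, columns=samples)
        pmap = pd.DataFrame({"locus_id": loci, "gene_id": locus_gene})
        methylation = MethylationMatrix(betas, pmap)
        truth_loci = pd.DataFrame(
            {
                "locus_id": loci,
                "gene_id": locus_gene,
                "true_dm": [1 if s else 0 for s in dm_sign],
                "sign": dm_sign,
            }
        )

    return SyntheticCohort(
        name=name,
        expression=expression,
        annotations=annotations,
        truth_samples=truth_samples,
        truth_genes=truth_genes,
        counts=counts,
        methylation=methylation,
        truth_loci=truth_loci,
        config=cfg,
    )


def generate_multi_cohort(
    cfg: GeneratorConfig,
    n_cohorts: int = 2,
    shared_de_fraction: float = 0.9,
    counts_cohort: int | None = None,
    methylation_cohort: int | None = 0,
) -> list[SyntheticCohort]:
    """Generate independent cohorts sharing a fraction of true DE genes.

    ``round(shared_de_fraction * n_de_genes)`` genes (with identical
    signs) are common to every cohort; the remaining DE genes are drawn
    disjointly per cohort, so ``shared_de_fraction=0`` gives disjoint DE
    sets. Cohort ``counts_cohort`` (if given) is emitted as raw counts in
    addition to log2 intensities; ``methylation_cohort`` selects which
    cohort carries the methylation arm (None for none).
    """
    if n_cohorts < 2:
        raise ValueError("need n_cohorts >= 2")
    if not (0.0 <= shared_de_fraction <= 1.0):
        raise ValueError("shared_de_fraction must lie in [0, 1]")
    n_shared = round(shared_de_fraction * cfg.n_de_genes)
    n_specific = cfg.n_de_genes - n_shared
    need = n_shared + n_cohorts * n_specific
    if need > cfg.n_genes:
        raise ValueError(
            f"cannot allocate {need} distinct DE genes from {cfg.n_genes}"
        )
    master = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    pool = list(master.permutation(cfg.n_genes))
    shared_idx = pool[:n_shared]
    shared_signs = {
        genes[i]: int(s)
        for i, s in zip(shared_idx, master.choice([-1, 1], size=n_shared))
    }
    offset = n_shared
    cohorts: list[SyntheticCohort] = []
    children = np.random.SeedSequence(cfg.seed).spawn(n_cohorts)
    for c in range(n_cohorts):
        specific_idx = pool[offset : offset + n_specific]
        offset += n_specific
        signs = dict(shared_signs)
        for i, s in zip(specific_idx, master.choice([-1, 1], size=n_specific)):
            signs[genes[i]] = int(s)
        cohorts.append(
            generate_cohort(
                cfg,
                name=f"cohort{c}",
                de_signs=signs,
                seed=children[c],
                with_counts=(c == counts_cohort),
                with_methylation=(c == methylation_cohort),
            )
        )
    return cohorts


def write_cohort(
    cohort: SyntheticCohort, outdir: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write a cohort's matrices, annotations and truth tables as TSV.

    Truth goes to separate ``truth_*.tsv`` files so analysis stages,
    which read only the observed files, cannot consume it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"cohort={cohort.name}", *comments]
    if cohort.config is not None:
        header.append(f"config={cohort.config}")
    mio.write_matrix(cohort.expression, outdir / "expression.tsv", header)
    mio.write_sample_annotations(
        cohort.annotations, outdir / "annotations.tsv", header
    )
    mio.write_table(cohort.truth_samples, outdir / "truth_samples.tsv", header)
    mio.write_table(cohort.truth_genes, outdir / "truth_genes.tsv", header)
    if cohort.counts is not None:
        mio.write_matrix(cohort.counts, outdir / "counts.tsv", header)
    if cohort.methylation is not None:
        mio.write_matrix(
            cohort.methylation.betas,
            outdir / "methylation.tsv",
            header,
            index_label="locus_id",
        )
        mio.write_table(
            cohort.methylation.promoter_map, outdir / "promoter_map.tsv", header
        )
    if cohort.truth_loci is not None:
        mio.write_table(cohort.truth_loci, outdir / "truth_loci.tsv", header)
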
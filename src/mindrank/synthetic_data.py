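"""Parameterized synthetic inputs with planted signal for every pipeline stage.

The generator emulates the structure of the real resources the pipeline
consumes — per-variant predictor score tables, a brain-eQTL table, histone
ChIP-seq peak tracks, population frequencies, gene annotation and gene-score
tables — on a toy genome, with a configurable class signal:

* the five functional predictor scores of disease-associated ("positive")
  variants are drawn with a mean shift (default 0.5 s.d.) relative to
  background variants;
* positives are enriched inside peaks of each histone mark (Bernoulli
  membership with class-specific probabilities) and are more likely to have
  a significant brain eQTL record;
* population frequencies are drawn from the same Beta for both classes,
  mirroring frequency-matched case/control construction;
* missingness is applied completely at random (MCAR) per source.

Because features are class-conditionally independent by construction, the
optimal (Bayes) classifier is the exact log-likelihood ratio, which the
generator evaluates by Monte Carlo — the reported Bayes AUC is an upper
bound on what any trained model can achieve on this data.

Stage 2 plants a subset of "disease" genes that receive shifted gene-score
distributions and extra high-scoring variants inside the gene body, so the
whole variant→gene pipeline is testable end to end without any download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    GeneAnnotation,
    GenomicVariant,
    IntervalTrack,
    ScoreTable,
    VariantSet,
)
from .gene_prioritization import GeneScoreSources
from .variant_features import (
    HISTONE_MARKS,
    PREDICTOR_SCORES,
    transform_qvalue,
)

_ALLELES = np.array(list("ACGT"))
_GRID = 1000          # bp between consecutive variant sites
_PEAK_HALF_WIDTH = 75  # bp each side of a member variant's base


@dataclass
class SimulationConfig:
    """All knobs of the generator; every rate is a probability in [0, 1].

    Defaults are the documented study conditions: 3,000 variants at 1:4
    class imbalance, five predictor scores shifted by 0.5 s.d. in positives,
    peak and eQTL enrichment chosen so the construction's Bayes AUC sits
    near 0.90.
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000}
    )
    n_positive: int = 600
    n_negative: int = 2400
    predictor_shift: float = 0.5        # s.d. units, positives vs negatives
    predictor_sd: float = 1.0
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "EIGEN": 0.10,
            "CADD": 0.05,
            "DANN": 0.05,
            "GWAVA": 0.15,
            "FATHMM": 0.10,
            "GNOMAD": 0.10,
        }
    )
    peak_prob_neg: float = 0.15         # P(in peak | background), per mark
    peak_prob_pos: float = 0.42         # P(in peak | disease), per mark
    n_decoy_peaks: int = 50             # extra peaks per mark away from variants
    eqtl_prob_neg: float = 0.10         # P(has significant brain eQTL | background)
    eqtl_prob_pos: float = 0.38
    eqtl_q_max: float = 0.05            # q-values drawn U(0, q_max)
    freq_beta: tuple[float, float] = (2.0, 8.0)  # both classes (matched)
    # --- stage 2 ---
    n_genes: int = 240
    disease_gene_fraction: float = 0.25
    gene_length: int = 20_000
    gene_spacing: int = 80_000
    extra_variants_per_disease_gene: int = 2
    gene_score_coverage: dict[str, float] = field(
        default_factory=lambda: {
            "RVIS": 0.8,
            "GTEx": 0.6,
            "haploinsufficiency": 0.7,
            "Phenolyzer": 0.5,
            "CNV": 0.3,
        }
    )
    gene_effect: float = 1.0            # scales every planted gene-level shift
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [
            *self.missing_rates.values(),
            self.peak_prob_neg,
            self.peak_prob_pos,
            self.eqtl_prob_neg,
            self.eqtl_prob_pos,
            self.disease_gene_fraction,
            *self.gene_score_coverage.values(),
        ]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.predictor_shift < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.peak_prob_pos > 0 and self.peak_prob_neg == 0 and self.n_decoy_peaks == 0:
            pass  # still feasible: peaks exist around positive members


def null_config(seed: int = 0) -> SimulationConfig:
    """A label-independent configuration: every planted effect switched off."""
    cfg = SimulationConfig(seed=seed)
    return replace(
        cfg,
        predictor_shift=0.0,
        peak_prob_pos=cfg.peak_prob_neg,
        eqtl_prob_pos=cfg.eqtl_prob_neg,
        gene_effect=0.0,
    )


@dataclass
class Stage1Data:
    """Everything the variant-scoring stage consumes, plus aligned labels."""

    variants: VariantSet
    score_tables: dict[str, ScoreTable]   # five predictors + GNOMAD
    eqtl_table: ScoreTable                # already transformed to [0.5, 1]
    eqtl_qvalues: dict[tuple, float]      # raw q per present key (for file output)
    mark_tracks: dict[str, IntervalTrack]
    labels: np.ndarray                    # aligned with the (sorted) VariantSet
    label_by_key: dict[tuple, int]
    bayes_auc: float
    config: SimulationConfig


@dataclass
class Stage2Data:
    """Gene universe, gene-score tables, labels, and the variant set augmented
    with the disease genes' extra planted variants (scoreable by stage 1)."""

    genes: list[GeneAnnotation]
    sources: GeneScoreSources
    gene_labels: dict[str, int]
    stage1_augmented: Stage1Data


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------


def _draw_variant_block(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    positions: list[tuple[str, int]],
    labels: np.ndarray,
):
    """Class-conditional draws for a block of variant sites.

    Returns per-variant records: alleles, predictor scores (with MCAR
    missingness), frequency, eQTL presence/q, and per-mark membership.
    """
    n = len(positions)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = _ALLELES[ref_idx]
    alts = _ALLELES[(ref_idx + alt_shift) % 4]

    shift = labels * cfg.predictor_shift * cfg.predictor_sd
    predictor_vals = {
        name: rng.normal(0.0, cfg.predictor_sd, size=n) + shift
        for name in PREDICTOR_SCORES
    }
    a, b = cfg.freq_beta
    freq = rng.beta(a, b, size=n)
    observed = {
        name: rng.random(n) >= cfg.missing_rates[name]
        for name in (*PREDICTOR_SCORES, "GNOMAD")
    }
    p_eqtl = np.where(labels == 1, cfg.eqtl_prob_pos, cfg.eqtl_prob_neg)
    has_eqtl = rng.random(n) < p_eqtl
    eqtl_q = rng.uniform(0.0, cfg.eqtl_q_max, size=n)
    p_peak = np.where(labels == 1, cfg.peak_prob_pos, cfg.peak_prob_neg)
    in_peak = {m: rng.random(n) < p_peak for m in HISTONE_MARKS}
    return refs, alts, predictor_vals, freq, observed, has_eqtl, eqtl_q, in_peak


def simulate_stage1(cfg: SimulationConfig) -> Stage1Data:
    """Generate the full stage-1 input bundle with planted class signal.

    Variant sites sit on a 1 kb grid so that the small peak intervals built
    around member variants can never spill onto a neighbouring site; peak
    membership is therefore exactly the drawn Bernoulli indicator.
    """
    if cfg.peak_prob_pos > 0 and not cfg.chromosomes:
        raise ValueError("peak enrichment requested but no chromosomes configured")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_positive + cfg.n_negative

    chrom_names = list(cfg.chromosomes)
    positions: list[tuple[str, int]] = []
    per_chrom = int(np.ceil(n / len(chrom_names)))
    for chrom in chrom_names:
        length = cfg.chromosomes[chrom]
        max_sites = (length - 10_000) // _GRID
        if per_chrom > max_sites:
            raise ValueError(f"chromosome {chrom} too short for {per_chrom} sites")
        positions.extend((chrom, 5_001 + i * _GRID) for i in range(per_chrom))
    positions = positions[:n]

    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=cfg.n_positive, replace=False)] = 1

    refs, alts, predictor_vals, freq, observed, has_eqtl, eqtl_q, in_peak = (
        _draw_variant_block(cfg, rng, positions, labels)
    )

    variants = [
        GenomicVariant(chrom, pos, refs[i], alts[i])
        for i, (chrom, pos) in enumerate(positions)
    ]
    return _bundle_stage1(
        cfg, rng, variants, labels, predictor_vals, freq, observed, has_eqtl, eqtl_q, in_peak
    )


def _bundle_stage1(
    cfg, rng, variants, labels, predictor_vals, freq, observed, has_eqtl, eqtl_q, in_peak
) -> Stage1Data:
    keys = [v.key for v in variants]
    score_tables = {}
    for name in PREDICTOR_SCORES:
        score_tables[name] = ScoreTable(
            name,
            {k: float(predictor_vals[name][i]) for i, k in enumerate(keys) if observed[name][i]},
        )
    score_tables["GNOMAD"] = ScoreTable(
        "GNOMAD", {k: float(freq[i]) for i, k in enumerate(keys) if observed["GNOMAD"][i]}
    )
    eqtl_qvalues = {k: float(eqtl_q[i]) for i, k in enumerate(keys) if has_eqtl[i]}
    eqtl_table = ScoreTable(
        "eQTL", {k: transform_qvalue(q) for k, q in eqtl_qvalues.items()}
    )

    mark_tracks = {}
    for m in HISTONE_MARKS:
        intervals = [
            (v.chrom, v.pos - 1 - _PEAK_HALF_WIDTH, v.pos - 1 + _PEAK_HALF_WIDTH + 1)
            for i, v in enumerate(variants)
            if in_peak[m][i]
        ]
        # decoy peaks in the gaps between grid sites (never cover a variant base)
        for _ in range(cfg.n_decoy_peaks):
            chrom = list(cfg.chromosomes)[rng.integers(len(cfg.chromosomes))]
            n_slots = (cfg.chromosomes[chrom] - 10_000) // _GRID
            centre = 5_000 + int(rng.integers(0, n_slots)) * _GRID + 500
            intervals.append((chrom, centre - _PEAK_HALF_WIDTH, centre + _PEAK_HALF_WIDTH))
        mark_tracks[m] = IntervalTrack(m, intervals)

    vs = VariantSet(variants, source_format="synthetic")
    label_by_key = {k: int(labels[i]) for i, k in enumerate(keys)}
    aligned = np.array([label_by_key[v.key] for v in vs], dtype=int)
    return Stage1Data(
        variants=vs,
        score_tables=score_tables,
        eqtl_table=eqtl_table,
        eqtl_qvalues=eqtl_qvalues,
        mark_tracks=mark_tracks,
        labels=aligned,
        label_by_key=label_by_key,
        bayes_auc=bayes_auc(cfg),
        config=cfg,
    )


def bayes_auc(cfg: SimulationConfig, n_draws: int = 100_000, seed: int | None = None) -> float:
    """Monte-Carlo AUC of the exact log-likelihood-ratio classifier.

    Features are class-conditionally independent by construction, so the
    optimal score is the sum of per-feature log likelihood ratios: Gaussian
    terms for the five shifted predictors and Bernoulli terms for peak
    membership and eQTL presence (frequency and the eQTL's q-value carry no
    class information).  Estimated on ``n_draws`` draws per class.
    """
    rng = np.random.default_rng(cfg.seed + 17 if seed is None else seed)
    delta = cfg.predictor_shift * cfg.predictor_sd
    sd = cfg.predictor_sd

    def llr_block(is_positive: bool) -> np.ndarray:
        mean = delta if is_positive else 0.0
        llr = np.zeros(n_draws)
        for _ in PREDICTOR_SCORES:
            x = rng.normal(mean, sd, size=n_draws)
            llr += (x * delta - delta**2 / 2.0) / sd**2
        for p_pos, p_neg, n_feat in (
            (cfg.peak_prob_pos, cfg.peak_prob_neg, len(HISTONE_MARKS)),
            (cfg.eqtl_prob_pos, cfg.eqtl_prob_neg, 1),
        ):
            if p_pos in (0.0, 1.0) or p_neg in (0.0, 1.0):
                if p_pos != p_neg:
                    # degenerate: a deterministic feature separates perfectly
                    llr += np.inf if is_positive else -np.inf
                continue
            l1 = np.log(p_pos / p_neg)
            l0 = np.log((1.0 - p_pos) / (1.0 - p_neg))
            p = p_pos if is_positive else p_neg
            for _ in range(n_feat):
                member = rng.random(n_draws) < p
                llr += np.where(member, l1, l0)
        return llr

    pos, neg = llr_block(True), llr_block(False)
    scores = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(n_draws), np.zeros(n_draws)])
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, scores))


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------


def simulate_stage2(cfg: SimulationConfig, stage1: Stage1Data) -> Stage2Data:
    """Plant a disease-gene subset on top of a stage-1 simulation.

    Disease genes receive (i) shifted RVIS/haploinsufficiency/Phenolyzer
    distributions, better CNV/GTEx coverage with smaller q-values and a
    higher de-novo-mutation rate, all scaled by ``cfg.gene_effect``; and
    (ii) ``cfg.extra_variants_per_disease_gene`` extra positive-class
    variants placed inside the gene body (offset from the 1 kb grid), so
    every disease gene has linked variant evidence within 100 kb by
    construction.
    """
    n_disease = int(round(cfg.n_genes * cfg.disease_gene_fraction))
    if n_disease > cfg.n_genes:
        raise ValueError("more disease genes than genes")
    rng = np.random.default_rng(cfg.seed + 1)

    chrom_names = list(cfg.chromosomes)
    genes: list[GeneAnnotation] = []
    per_chrom = int(np.ceil(cfg.n_genes / len(chrom_names)))
    i = 0
    for chrom in chrom_names:
        length = cfg.chromosomes[chrom]
        for j in range(per_chrom):
            if i >= cfg.n_genes:
                break
            start = 10_001 + j * cfg.gene_spacing
            end = start + cfg.gene_length - 1
            if end > length:
                raise ValueError(f"chromosome {chrom} too short for {per_chrom} genes")
            genes.append(GeneAnnotation(f"G{i + 1:04d}", chrom, start, end))
            i += 1

    disease_idx = rng.choice(cfg.n_genes, size=n_disease, replace=False)
    gene_labels = {g.gene_id: 0 for g in genes}
    for idx in disease_idx:
        gene_labels[genes[idx].gene_id] = 1

    eff = cfg.gene_effect
    cov = cfg.gene_score_coverage
    rvis, gtex, haplo, pheno, cnv, dnm = {}, {}, {}, {}, {}, {}
    for g in genes:
        dis = gene_labels[g.gene_id]
        if rng.random() < cov["RVIS"]:
            rvis[g.gene_id] = float(np.clip(rng.normal(0.40 + 0.25 * eff * dis, 0.15), 0, 1))
        if rng.random() < min(1.0, cov["GTEx"] * (1 + 0.3 * eff * dis)):
            gtex[g.gene_id] = transform_qvalue(
                float(rng.uniform(0, 0.05) * (1 - 0.6 * eff * dis)), clamp_low=0.0
            )
        if rng.random() < cov["haploinsufficiency"]:
            haplo[g.gene_id] = float(np.clip(rng.beta(2 + 3 * eff * dis, 4), 0, 1))
        if rng.random() < cov["Phenolyzer"]:
            pheno[g.gene_id] = float(np.clip(rng.normal(0.30 + 0.30 * eff * dis, 0.15), 0, 1))
        if rng.random() < min(1.0, cov["CNV"] * (1 + 1.0 * eff * dis)):
            cnv[g.gene_id] = float(rng.uniform(0, 0.05))
        count = rng.poisson(0.5 + 2.5 * eff * dis)
        if count > 0:
            dnm[g.gene_id] = int(count)

    # extra planted positive variants inside disease gene bodies
    extra_positions: list[tuple[str, int]] = []
    for idx in disease_idx:
        g = genes[idx]
        for e in range(cfg.extra_variants_per_disease_gene):
            # offset ~250 bp off the grid keeps new sites clear of both the
            # member peaks (grid +/- 75 bp) and the decoy peaks (grid + 500)
            pos = g.start + 249 + e * _GRID
            extra_positions.append((g.chrom, pos))

    n_extra = len(extra_positions)
    if n_extra:
        extra_labels = np.ones(n_extra, dtype=int)
        refs, alts, pvals, freq, observed, has_eqtl, eqtl_q, in_peak = _draw_variant_block(
            cfg, rng, extra_positions, extra_labels
        )
        extra_variants = [
            GenomicVariant(chrom, pos, refs[i], alts[i])
            for i, (chrom, pos) in enumerate(extra_positions)
        ]
        merged = _merge_stage1(
            stage1, extra_variants, extra_labels, pvals, freq, observed, has_eqtl, eqtl_q, in_peak
        )
    else:
        merged = stage1

    sources = GeneScoreSources(
        rvis=rvis, gtex=gtex, haploinsufficiency=haplo, phenolyzer=pheno,
        cnv=cnv, dnm_counts=dnm,
    )
    return Stage2Data(
        genes=genes, sources=sources, gene_labels=gene_labels, stage1_augmented=merged
    )


def _merge_stage1(
    s1: Stage1Data, variants, labels, pvals, freq, observed, has_eqtl, eqtl_q, in_peak
) -> Stage1Data:
    keys = [v.key for v in variants]
    tables = {}
    for name in PREDICTOR_SCORES:
        scores = dict(s1.score_tables[name].scores)
        scores.update(
            {k: float(pvals[name][i]) for i, k in enumerate(keys) if observed[name][i]}
        )
        tables[name] = ScoreTable(name, scores)
    gnomad = dict(s1.score_tables["GNOMAD"].scores)
    gnomad.update({k: float(freq[i]) for i, k in enumerate(keys) if observed["GNOMAD"][i]})
    tables["GNOMAD"] = ScoreTable("GNOMAD", gnomad)

    eqtl_qvalues = dict(s1.eqtl_qvalues)
    eqtl_qvalues.update({k: float(eqtl_q[i]) for i, k in enumerate(keys) if has_eqtl[i]})
    eqtl_table = ScoreTable("eQTL", {k: transform_qvalue(q) for k, q in eqtl_qvalues.items()})

    mark_tracks = {}
    for m, track in s1.mark_tracks.items():
        intervals = list(track.intervals) + [
            (v.chrom, v.pos - 1 - _PEAK_HALF_WIDTH, v.pos - 1 + _PEAK_HALF_WIDTH + 1)
            for i, v in enumerate(variants)
            if in_peak[m][i]
        ]
        mark_tracks[m] = IntervalTrack(m, intervals)

    all_variants = list(s1.variants) + list(variants)
    vs = VariantSet(all_variants, source_format="synthetic")
    label_by_key = dict(s1.label_by_key)
    label_by_key.update({k: int(labels[i]) for i, k in enumerate(keys)})
    aligned = np.array([label_by_key[v.key] for v in vs], dtype=int)
    return Stage1Data(
        variants=vs,
        score_tables=tables,
        eqtl_table=eqtl_table,
        eqtl_qvalues=eqtl_qvalues,
        mark_tracks=mark_tracks,
        labels=aligned,
        label_by_key=label_by_key,
        bayes_auc=s1.bayes_auc,
        config=s1.config,
    )


# ---------------------------------------------------------------------------
# File output (every format consumed by genomic_io)
# ---------------------------------------------------------------------------


def write_stage1(data: Stage1Data, outdir: str | Path) -> dict[str, str]:
    """Write the stage-1 bundle as files and return the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    vcf_path = outdir / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in data.config.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in data.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")
    paths["variants"] = str(vcf_path)

    for name, table in data.score_tables.items():
        p = outdir / f"scores_{name}.tsv"
        rows = [(*k, s) for k, s in sorted(table.scores.items())]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "score"]).to_csv(
            p, sep="\t", index=False
        )
        paths[f"scores_{name}"] = str(p)

    eqtl_path = outdir / "eqtl.tsv"
    rows = [(*k, f"G{k[1] % 997:03d}", q) for k, q in sorted(data.eqtl_qvalues.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "score"]).to_csv(
        eqtl_path, sep="\t", index=False
    )
    paths["eqtl"] = str(eqtl_path)

    for m, track in data.mark_tracks.items():
        p = outdir / f"peaks_{m}.bed"
        with open(p, "w") as fh:
            for chrom, start, end in sorted(track.intervals):
                fh.write(f"{chrom}\t{start}\t{end}\n")
        paths[f"peaks_{m}"] = str(p)

    labels_path = outdir / "labels.tsv"
    rows = [(*v.key, data.labels[i]) for i, v in enumerate(data.variants)]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "label"]).to_csv(
        labels_path, sep="\t", index=False
    )
    paths["labels"] = str(labels_path)

    manifest = {
        "paths": paths,
        "config": _jsonable(asdict(data.config)),
        "bayes_auc": data.bayes_auc,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)
    return paths


def write_stage2(data: Stage2Data, outdir: str | Path) -> dict[str, str]:
    """Write gene annotation, gene-score tables and gene labels; also rewrites
    the augmented stage-1 bundle (extra planted variants included)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_stage1(data.stage1_augmented, outdir)

    genes_path = outdir / "genes.tsv"
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end) for g in data.genes],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(genes_path, sep="\t", index=False)
    paths["genes"] = str(genes_path)

    tables = {
        "rvis": data.sources.rvis,
        "gtex": data.sources.gtex,
        "haploinsufficiency": data.sources.haploinsufficiency,
        "phenolyzer": data.sources.phenolyzer,
        "cnv": data.sources.cnv,
        "dnm": data.sources.dnm_counts,
    }
    for name, table in tables.items():
        p = outdir / f"gene_{name}.tsv"
        col = "count" if name == "dnm" else "score"
        pd.DataFrame(sorted(table.items()), columns=["gene", col]).to_csv(
            p, sep="\t", index=False
        )
        paths[f"gene_{name}"] = str(p)

    labels_path = outdir / "gene_labels.tsv"
    pd.DataFrame(
        sorted(data.gene_labels.items()), columns=["gene", "label"]
    ).to_csv(labels_path, sep="\t", index=False)
    paths["gene_labels"] = str(labels_path)

    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    manifest["paths"] = {k: v for k, v in paths.items() if k != "manifest"}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
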
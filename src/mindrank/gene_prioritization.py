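"""Stage 2: from scored variants to ranked candidate genes.

Non-coding variants carry no gene label, so each scored variant is linked to
every gene whose body lies within 100 kb of it; a gene harbouring several
linked variants aggregates their stage-1 scores (default: maximum — the
strongest single piece of variant evidence).  The aggregated variant score
joins six gene-level predictors into the 7-slot feature vector

    F = (variant_score, RVIS, GTEx, haploinsufficiency, Phenolyzer, CNV, DNM)

with per-feature fill rules for genes absent from a source table:

* RVIS               -> 0
* GTEx               -> EMR (training-set missing rate), q-values inverted
                        to 1 - q and restricted to significant (q < 0.05)
                        records at load
* haploinsufficiency -> EMR
* Phenolyzer         -> EMR
* CNV                -> 0.5, q-values inverted to 1 - q
* de novo mutations  -> per-gene count min-max normalized to [0, 1]; 0 for
                        genes with none

so every feature is total over the gene universe.  The same feed-forward
scorer as stage 1 then produces the final gene prioritization score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneAnnotation, GenomicVariant
from .missing_data import EmrConfig, compute_emr, emr_fill
from .scorer import ScorerModel, forward
from .variant_features import FeatureMatrix, transform_qvalue

logger = logging.getLogger(__name__)

#: Fixed stage-2 feature order.
GENE_FEATURES = (
    "variant_score",
    "RVIS",
    "GTEx",
    "haploinsufficiency",
    "Phenolyzer",
    "CNV",
    "DNM",
)
#: Gene features whose absence is filled with the training missing rate.
EMR_FILLED = ("GTEx", "haploinsufficiency", "Phenolyzer")

RVIS_ABSENT_FILL = 0.0
CNV_ABSENT_FILL = 0.5
MAX_LINK_DISTANCE = 100_000  # bp, boundary inclusive
GTEX_Q_THRESHOLD = 0.05  # records with q >= threshold are rejected at load


@dataclass(frozen=True)
class VariantGeneLink:
    variant_key: tuple
    gene_id: str
    distance: int  # bp; 0 if the variant lies inside the gene body

    def __post_init__(self) -> None:
        if self.distance > MAX_LINK_DISTANCE:
            raise ValueError(f"link distance {self.distance} exceeds {MAX_LINK_DISTANCE}")


def variant_gene_distance(v: GenomicVariant, g: GeneAnnotation) -> int | None:
    """Distance in bp from a variant to a gene body; None on different chromosomes."""
    if v.chrom != g.chrom:
        return None
    if g.start <= v.pos <= g.end:
        return 0
    return g.start - v.pos if v.pos < g.start else v.pos - g.end


def link_variants_to_genes(
    variants: list[GenomicVariant],
    genes: list[GeneAnnotation],
    max_dist: int = MAX_LINK_DISTANCE,
) -> list[VariantGeneLink]:
    """Link each variant to every gene within ``max_dist`` bp (inclusive).

    A variant may link to several genes; variants with no gene in range are
    counted and logged but produce no link.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.start)

    links: list[VariantGeneLink] = []
    n_unlinked = 0
    for v in variants:
        found = False
        for g in by_chrom.get(v.chrom, ()):
            if g.start - v.pos > max_dist:
                break  # genes sorted by start; none further right can match
            dist = variant_gene_distance(v, g)
            if dist is not None and dist <= max_dist:
                links.append(VariantGeneLink(v.key, g.gene_id, dist))
                found = True
        if not found:
            n_unlinked += 1
    if n_unlinked:
        logger.info("%d variants had no gene within %d bp", n_unlinked, max_dist)
    return links


def aggregate_variant_scores(
    links: list[VariantGeneLink],
    variant_scores: dict[tuple, float],
    genes: list[GeneAnnotation],
    mode: str = "max",
) -> dict[str, float]:
    """Reduce the stage-1 scores of each gene's linked variants to one scalar.

    Modes: ``max`` (strongest evidence, default), ``mean``, and
    ``count-weighted`` (mean times the saturating factor
    ``n_linked / (n_linked + 1)``, rewarding recurrently hit genes).  Genes
    with no linked variant get 0.
    """
    if mode not in ("max", "mean", "count-weighted"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    per_gene: dict[str, list[float]] = {}
    for link in links:
        if link.variant_key not in variant_scores:
            raise ValueError(f"linked variant {link.variant_key} has no stage-1 score")
        per_gene.setdefault(link.gene_id, []).append(variant_scores[link.variant_key])
    out: dict[str, float] = {}
    n_flagged = 0
    for g in genes:
        scores = per_gene.get(g.gene_id)
        if not scores:
            out[g.gene_id] = 0.0
            n_flagged += 1
            continue
        if mode == "max":
            out[g.gene_id] = float(max(scores))
        elif mode == "mean":
            out[g.gene_id] = float(np.mean(scores))
        else:
            out[g.gene_id] = float(np.mean(scores)) * len(scores) / (len(scores) + 1.0)
    if n_flagged:
        logger.info("%d genes had no linked variant (score 0)", n_flagged)
    return out


# ---------------------------------------------------------------------------
# Per-source gene feature functions
# ---------------------------------------------------------------------------


def load_gtex_table(records: pd.DataFrame, q_threshold: float = GTEX_Q_THRESHOLD) -> dict[str, float]:
    """Significant expression-association evidence per gene.

    ``records`` has columns gene, q; rows with q >= ``q_threshold`` are
    rejected at load.  Several records per gene keep the strongest (largest
    1 - q) evidence.
    """
    keep = records[records["q"] < q_threshold]
    n_rejected = len(records) - len(keep)
    if n_rejected:
        logger.info("GTEx load: rejected %d records with q >= %g", n_rejected, q_threshold)
    out: dict[str, float] = {}
    for r in keep.itertuples(index=False):
        val = transform_qvalue(float(r.q), clamp_low=0.0)
        gene = str(r.gene)
        if gene not in out or val > out[gene]:
            out[gene] = val
    return out


def gtex_feature(table: dict[str, float], gene: str, emr: float) -> float:
    """Transformed significant q-value if present; EMR fill if absent."""
    return table.get(gene, emr)


def rvis_feature(table: dict[str, float], gene: str) -> float:
    """RVIS score if present; 0 if the gene has none."""
    return table.get(gene, RVIS_ABSENT_FILL)


def haploinsufficiency_feature(table: dict[str, float], gene: str, emr: float) -> float:
    """Haploinsufficiency probability if present; EMR fill if absent."""
    return table.get(gene, emr)


def phenolyzer_feature(table: dict[str, float], gene: str, emr: float) -> float:
    """Phenotype-driven relevance score if present; EMR fill if absent."""
    return table.get(gene, emr)


def cnv_feature(table: dict[str, float], gene: str) -> float:
    """Copy-number association evidence: 1 - q if present, 0.5 if absent.

    The inversion keeps orientation consistent with every other feature
    (larger = stronger disease evidence).
    """
    if gene not in table:
        return CNV_ABSENT_FILL
    return transform_qvalue(table[gene], clamp_low=0.0)


def dnm_feature(counts: dict[str, int], genes: list[str]) -> dict[str, float]:
    """De-novo-mutation burden: per-gene count min-max normalized over the
    gene universe; genes with no recorded mutation get 0."""
    for g, c in counts.items():
        if c < 0:
            raise ValueError(f"negative DNM count for gene {g}")
    raw = np.array([counts.get(g, 0) for g in genes], dtype=float)
    lo, hi = raw.min() if len(raw) else 0.0, raw.max() if len(raw) else 0.0
    if hi > lo:
        norm = (raw - lo) / (hi - lo)
    else:
        norm = np.zeros_like(raw)
    return dict(zip(genes, norm))


@dataclass
class GeneScoreSources:
    """All stage-2 annotation tables keyed by gene id.

    ``gtex``, ``haploinsufficiency`` and ``phenolyzer`` carry per-feature
    missingness that EMR fills must be trained for; ``cnv`` holds raw
    q-values (inverted on use); ``dnm_counts`` holds per-gene mutation
    counts.
    """

    rvis: dict[str, float]
    gtex: dict[str, float]
    haploinsufficiency: dict[str, float]
    phenolyzer: dict[str, float]
    cnv: dict[str, float]
    dnm_counts: dict[str, int]


def fit_emr(sources: GeneScoreSources, training_genes: list[str]) -> EmrConfig:
    """Training-set missing rates for the EMR-filled features."""
    tables = {
        "GTEx": sources.gtex,
        "haploinsufficiency": sources.haploinsufficiency,
        "Phenolyzer": sources.phenolyzer,
    }
    emr = {
        name: compute_emr(np.array([g not in table for g in training_genes]))
        for name, table in tables.items()
    }
    return EmrConfig(emr=emr)


def assemble_gene_features(
    genes: list[GeneAnnotation],
    variant_score_per_gene: dict[str, float],
    sources: GeneScoreSources,
    emr: EmrConfig,
) -> FeatureMatrix:
    """Build the 7-column stage-2 FeatureMatrix; every feature is total."""
    gene_ids = [g.gene_id for g in genes]
    dnm = dnm_feature(sources.dnm_counts, gene_ids)
    rows = []
    for gid in gene_ids:
        rows.append(
            [
                variant_score_per_gene.get(gid, 0.0),
                rvis_feature(sources.rvis, gid),
                gtex_feature(sources.gtex, gid, emr.emr["GTEx"]),
                haploinsufficiency_feature(
                    sources.haploinsufficiency, gid, emr.emr["haploinsufficiency"]
                ),
                phenolyzer_feature(sources.phenolyzer, gid, emr.emr["Phenolyzer"]),
                cnv_feature(sources.cnv, gid),
                dnm[gid],
            ]
        )
    values = np.asarray(rows, dtype=float)
    assert values.shape[1] == len(GENE_FEATURES) == 7
    return FeatureMatrix(gene_ids, list(GENE_FEATURES), values)


def rank_genes(features: FeatureMatrix, model: ScorerModel) -> pd.DataFrame:
    """Score and rank genes; the output keeps full feature provenance per row.

    The model must have been trained on :data:`GENE_FEATURES` in order; any
    column mismatch is an error, never a silent misalignment.
    """
    if list(features.columns) != list(GENE_FEATURES):
        raise ValueError(
            f"feature columns {features.columns} do not match expected {list(GENE_FEATURES)}"
        )
    if features.mask.any():
        raise ValueError("gene features must be total before ranking")
    scores = forward(model, features.values)
    df = features.to_dataframe(masked_as_nan=False).reset_index(names="gene")
    df["score"] = scores
    return df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )
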
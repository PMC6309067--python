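"""Stage-1 feature assembly for non-coding variants.

Every variant is described by an 11-slot feature vector

    F = (EIGEN, CADD, DANN, GWAVA, FATHMM, GNOMAD,
         eQTL, H3K4me3, H3K4me1, H3K27me3, H3K27Ac)

Five pre-computed functional predictor scores and the population allele
frequency may be MISSING for a given variant (they are imputed downstream);
the eQTL evidence and the four histone-mark peak memberships are defined by
rule for every variant and are therefore always observed:

* a variant with a known brain eQTL receives its transformed association
  score (by default 1 - q clamped to [0.5, 1]); a variant without one
  receives 0.5;
* each mark contributes a {0,1} indicator for whether the variant lies in
  at least one ChIP-seq peak of that mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import (
    MISSING,
    GenomicVariant,
    IntervalTrack,
    ScoreTable,
    VariantSet,
    query_interval_membership,
)

#: Names of the five functional predictor scores (imputable).
PREDICTOR_SCORES = ("EIGEN", "CADD", "DANN", "GWAVA", "FATHMM")
#: Names of the four histone-mark peak indicators (rule-based, total).
HISTONE_MARKS = ("H3K4me3", "H3K4me1", "H3K27me3", "H3K27Ac")
#: Fixed stage-1 feature order.
STAGE1_FEATURES = (*PREDICTOR_SCORES, "GNOMAD", "eQTL", *HISTONE_MARKS)
#: Columns that may carry missing values (everything else is total by rule).
STAGE1_MASKABLE = (*PREDICTOR_SCORES, "GNOMAD")

EQTL_ABSENT_FILL = 0.5  # evidence value for a variant with no known brain eQTL


@dataclass
class FeatureMatrix:
    """Entities x named features with an explicit missingness mask.

    ``values[i, j]`` is meaningful only where ``mask[i, j]`` is False; masked
    cells hold NaN placeholders and are replaced by imputation downstream.
    """

    keys: list
    columns: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.keys), len(self.columns)):
            raise ValueError("shape inconsistent with keys/columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_dataframe(self, masked_as_nan: bool = True) -> pd.DataFrame:
        vals = self.values.copy()
        if masked_as_nan:
            vals[self.mask] = np.nan
        return pd.DataFrame(vals, columns=self.columns, index=pd.Index(self.keys))

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.keys), list(self.columns), self.values.copy(), self.mask.copy()
        )


def load_eqtl_table(path, strip_chr: bool = True) -> ScoreTable:
    """Load a brain-eQTL TSV (chrom, pos, ref, alt, gene, score).

    The score column holds association q-values; they are transformed to
    evidence scores ``1 - q`` clamped to [0.5, 1] at load, and a variant
    with several records (one per target gene) keeps the strongest.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if (df["score"] < 0).any() or (df["score"] > 1).any():
        raise ValueError(f"{path}: eQTL q-values outside [0, 1]")
    from .genomic_io import normalize_chrom

    scores: dict[tuple, float] = {}
    for r in df.itertuples(index=False):
        key = (normalize_chrom(str(r.chrom), strip_chr), int(r.pos), str(r.ref), str(r.alt))
        val = transform_qvalue(float(r.score))
        if key not in scores or val > scores[key]:
            scores[key] = val
    return ScoreTable(source="eQTL", scores=scores, key_mode="allele")


def transform_qvalue(q: float, clamp_low: float = 0.5) -> float:
    """Map an association q-value to an evidence score in [clamp_low, 1].

    Significant-association evidence is encoded as ``1 - q`` so that larger
    means stronger; clamping to ``clamp_low`` keeps any present record at
    least as strong as the absent-record default.
    """
    return float(min(1.0, max(clamp_low, 1.0 - q)))


def enhancer_promoter_feature(
    tracks: dict[str, IntervalTrack], v: GenomicVariant
) -> dict[str, int]:
    """Per-mark {0,1} peak membership for one variant.

    ``tracks`` maps each histone mark name to its peak track; every mark in
    :data:`HISTONE_MARKS` must be present.
    """
    missing = [m for m in HISTONE_MARKS if m not in tracks]
    if missing:
        raise ValueError(f"missing histone mark tracks: {missing}")
    return {m: query_interval_membership(tracks[m], v) for m in HISTONE_MARKS}


def eqtl_feature(eqtl_table: ScoreTable, v: GenomicVariant) -> float:
    """Brain-eQTL evidence in [0, 1]: table value if present, else 0.5."""
    val = eqtl_table.lookup(v)
    if val is MISSING:
        return EQTL_ABSENT_FILL
    if not 0.0 <= val <= 1.0:
        raise ValueError(f"eQTL score {val} outside [0, 1] for {v.key}")
    return float(val)


def assemble_variant_features(
    vs: VariantSet,
    score_tables: dict[str, ScoreTable],
    eqtl_table: ScoreTable,
    mark_tracks: dict[str, IntervalTrack],
    gnomad_table: ScoreTable | None = None,
) -> FeatureMatrix:
    """Build the stage-1 FeatureMatrix: one row per variant, 11 fixed columns.

    ``score_tables`` maps each predictor name in :data:`PREDICTOR_SCORES` to
    its table; ``gnomad_table`` holds population allele frequencies (may be
    passed inside ``score_tables`` under ``"GNOMAD"`` instead).  Absent
    predictor/frequency records are recorded in the mask — imputation is a
    separate downstream step.  The eQTL and mark columns are total by rule
    and never masked.
    """
    tables = dict(score_tables)
    if gnomad_table is not None:
        tables["GNOMAD"] = gnomad_table
    missing_tables = [s for s in STAGE1_MASKABLE if s not in tables]
    if missing_tables:
        raise ValueError(f"missing score tables: {missing_tables}")

    n = len(vs)
    p = len(STAGE1_FEATURES)
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    col = {name: j for j, name in enumerate(STAGE1_FEATURES)}

    for i, v in enumerate(vs):
        for name in STAGE1_MASKABLE:
            val = tables[name].lookup(v)
            if val is MISSING:
                mask[i, col[name]] = True
            else:
                values[i, col[name]] = float(val)
        values[i, col["eQTL"]] = eqtl_feature(eqtl_table, v)
        marks = enhancer_promoter_feature(mark_tracks, v)
        for m, indicator in marks.items():
            values[i, col[m]] = indicator

    assert len(STAGE1_FEATURES) == 11
    return FeatureMatrix(vs.keys, list(STAGE1_FEATURES), values, mask)


def pairwise_feature_correlation(m: FeatureMatrix) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between feature columns.

    Used as a redundancy/collinearity diagnostic on training matrices.
    Constant columns yield NaN (undefined correlation), never a fabricated
    number; the diagonal is 1 for every non-constant column.
    """
    df = m.to_dataframe(masked_as_nan=True)
    corr = df.corr(method="pearson", min_periods=3)
    for c in df.columns:
        obs = df[c].dropna()
        if len(obs) >= 2 and obs.nunique() > 1:
            corr.loc[c, c] = 1.0
    return corr
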
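"""Subcellular-disposition calls from targeting predictions.

Each candidate protein carries a signal-peptide prediction (type,
cleavage probability and position) and a transmembrane-segment count.
The classification rule: a Sec/Tat protein without TM segments is
exported; otherwise 0 TM segments = cytoplasmic, 1 = monotopic,
more = polytopic.  A membrane protein with a cleaved signal peptide is
labeled by its TM count, not as exported.

A toy sliding-window Kyte–Doolittle hydropathy predictor is included so
synthetic bundles can be classified without external neural predictors.
The package ships a curated table of targeting predictions for the 23
cluster orthogroups of the pseudomurein candidate set
(``data/cluster_og_targeting.tsv``); TM counts reported there as ">1"
are encoded as 2, which classifies identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

LOCALIZATION_LABELS = ("exported", "cytoplasmic", "monotopic", "polytopic")

# Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class TargetingPrediction:
    protein_id: str
    sp_type: str  # Sec | Tat | other
    cleavage_prob: float
    cleavage_pos: int | None
    tm_count: int

    def __post_init__(self) -> None:
        if self.cleavage_prob > 0 and self.cleavage_pos is None:
            raise ValueError(f"{self.protein_id}: cleavage_prob > 0 requires cleavage_pos")
        if self.cleavage_prob == 0 and self.cleavage_pos is not None:
            raise ValueError(f"{self.protein_id}: cleavage_pos given with zero probability")


def strip_signal_peptide(
    sequence: str, prediction: TargetingPrediction, prob_min: float = 0.1
) -> str:
    """Remove the predicted signal peptide when the cleavage-site
    probability reaches ``prob_min`` (inclusive); otherwise return the
    sequence unchanged."""
    if prediction.cleavage_prob < prob_min or prediction.cleavage_pos is None:
        return sequence
    if prediction.cleavage_pos >= len(sequence):
        raise ValueError(
            f"{prediction.protein_id}: cleavage position {prediction.cleavage_pos} "
            f"outside sequence of length {len(sequence)}"
        )
    return sequence[prediction.cleavage_pos:]


def classify_localization(prediction: TargetingPrediction) -> str:
    """Classify a protein as exported / cytoplasmic / monotopic / polytopic."""
    if prediction.tm_count < 0:
        raise ValueError("tm_count must be >= 0")
    if prediction.sp_type in ("Sec", "Tat") and prediction.tm_count == 0:
        return "exported"
    if prediction.tm_count == 0:
        return "cytoplasmic"
    if prediction.tm_count == 1:
        return "monotopic"
    return "polytopic"


def predict_tm_hydropathy(sequence: str, window: int = 19, threshold: float = 1.6) -> int:
    """Count non-overlapping windows of mean hydropathy >= threshold.

    A greedy left-to-right scan: when a window fires, scanning resumes
    after it.  Sequences shorter than the window yield 0 with a warning.
    """
    if len(sequence) < window:
        warnings.warn(
            f"sequence length {len(sequence)} < window {window}; returning 0",
            stacklevel=2,
        )
        return 0
    values = [KYTE_DOOLITTLE.get(c, 0.0) for c in sequence]
    count = 0
    i = 0
    while i + window <= len(values):
        if sum(values[i:i + window]) / window >= threshold:
            count += 1
            i += window
        else:
            i += 1
    return count


def read_targeting_table(path: str | Path) -> dict[str, TargetingPrediction]:
    """Read a targeting-prediction TSV
    (protein_id, sp_type, cleavage_prob, cleavage_pos, tm_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"cleavage_pos": "Int64"})
    out = {}
    for row in df.itertuples(index=False):
        pos = None if pd.isna(row.cleavage_pos) else int(row.cleavage_pos)
        out[row.protein_id] = TargetingPrediction(
            row.protein_id, row.sp_type, float(row.cleavage_prob), pos, int(row.tm_count)
        )
    return out


def load_cluster_og_targeting() -> pd.DataFrame:
    """The curated targeting table for the 23 cluster orthogroups."""
    with resources.files("panpm.data").joinpath("cluster_og_targeting.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
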
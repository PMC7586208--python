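"""Ranking of candidate all-atom structural models.

Homology-completion runs emit several candidate models together with two
quality measures: the DOPE statistical-potential energy (dimensionless,
lower is better) and the heavy-atom RMSD to the template structure (Å,
lower is better).  The two criteria can disagree; the ranking here is
lexicographic with DOPE primary and RMSD as the tie-break (model id breaks
remaining ties), which is the only deterministic rule consistent with
picking the lowest-energy model while still consulting RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError

__all__ = ["ModelScore", "rank_models", "read_model_scores", "write_model_scores"]


@dataclass(frozen=True)
class ModelScore:
    """Quality scores for one candidate model."""

    model_id: int
    rmsd: float  # Å vs the reference structure
    dope: float  # statistical-potential energy, lower = better

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def rank_models(scores: list[ModelScore]) -> list[ModelScore]:
    """Sort models best-first: DOPE ascending, then RMSD, then model id.

    Raises on an empty list or duplicate model ids.  The result is a
    permutation of the input and the operation is idempotent.
    """
    if not scores:
        raise ValueError("cannot rank an empty score list")
    ids = [s.model_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids in score list")
    return sorted(scores, key=lambda s: (s.dope, s.rmsd, s.model_id))


def read_model_scores(path: str | Path) -> list[ModelScore]:
    """Read a model-score table (TSV: model_id, rmsd_A, dope)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("model_id", "rmsd_A", "dope") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        ModelScore(model_id=int(r.model_id), rmsd=float(r.rmsd_A), dope=float(r.dope))
        for r in df.itertuples()
    ]


def write_model_scores(scores: list[ModelScore], path: str | Path) -> None:
    pd.DataFrame(
        {
            "model_id": [s.model_id for s in scores],
            "rmsd_A": [s.rmsd for s in scores],
            "dope": [s.dope for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)
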
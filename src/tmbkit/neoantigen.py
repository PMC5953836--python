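"""Mutant-peptide window enumeration and neoantigen-candidate counting.

A candidate neoantigen is a mutant 8-11mer peptide predicted to bind at least
one of the patient's class-I HLA alleles with IC50 <= 500 nM (strong binder:
<= 50 nM). Binding affinities come from an external predictor and are
consumed as a table; this module enumerates the peptide windows, applies the
affinity thresholds, and aggregates per-patient burdens, optionally
restricted to clonal mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .clonality import CLONAL, UNRESOLVED
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

PEPTIDE_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class NeoantigenProfile:
    """Per-patient candidate neoantigen burdens."""

    patient_id: str
    n_candidates_500: int
    n_candidates_50: int
    n_clonal_candidates_500: int | None = None


def enumerate_mutant_peptides(
    protein_length: int,
    mutated_position: int,
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
    multi_residue: bool = False,
) -> list[tuple[int, int]]:
    """Enumerate (start, length) windows of mutant peptides.

    For a single-residue change, every window of each length that lies fully
    inside the protein and contains the mutated position. For multi-residue
    variants (``multi_residue=True``, e.g. frameshifts), every window
    containing the variant start or lying downstream of it, since all
    downstream sequence is altered. Coordinates are 1-based.
    """
    if not (1 <= mutated_position <= protein_length):
        raise ParameterError(
            f"mutated_position {mutated_position} outside 1..{protein_length}"
        )
    windows = []
    for length in lengths:
        if length > protein_length:
            continue
        first = max(1, mutated_position - length + 1)
        last = protein_length - length + 1 if multi_residue else min(
            mutated_position, protein_length - length + 1
        )
        windows.extend((start, length) for start in range(first, last + 1))
    return windows


def _require_single_patient(affinities: pd.DataFrame) -> None:
    patients = affinities["patient_id"].unique()
    if len(patients) > 1:
        raise ValidationError(
            f"affinity rows span multiple patients: {sorted(patients)}"
        )


def count_candidates(
    affinities: pd.DataFrame,
    threshold_nm: float = 500.0,
    unit: str = "peptide",
) -> int:
    """Count one patient's candidate neoantigens at an IC50 threshold.

    With ``unit="peptide"`` (default) a peptide binding several of the
    patient's alleles counts once: distinct (mutation_key, peptide) pairs
    whose minimum IC50 across alleles is <= threshold (inclusive).
    ``unit="peptide_allele"`` counts each qualifying peptide-allele pair.
    """
    if threshold_nm <= 0:
        raise ParameterError(f"threshold_nm must be positive, got {threshold_nm}")
    if unit not in ("peptide", "peptide_allele"):
        raise ParameterError(f"unknown counting unit {unit!r}")
    if affinities.empty:
        return 0
    _require_single_patient(affinities)
    hits = affinities["ic50_nm"] <= threshold_nm
    if unit == "peptide_allele":
        return int(hits.sum())
    return int(
        affinities.loc[hits, ["mutation_key", "peptide"]]
        .drop_duplicates()
        .shape[0]
    )


def clonal_neoantigen_burden(
    affinities: pd.DataFrame,
    clonality: Mapping[str, str],
    threshold_nm: float = 500.0,
    unit: str = "peptide",
) -> int:
    """Candidate count restricted to mutations classified clonal.

    Mutations absent from the clonality map or marked unresolved are excluded
    from the count (with a logged tally), never guessed.
    """
    if affinities.empty:
        return 0
    _require_single_patient(affinities)
    status = affinities["mutation_key"].map(lambda k: clonality.get(k, UNRESOLVED))
    n_unresolved = affinities.loc[status == UNRESOLVED, "mutation_key"].nunique()
    if n_unresolved:
        logger.info(
            "excluding %d mutation(s) with unresolved clonality from the "
            "clonal neoantigen burden", n_unresolved
        )
    return count_candidates(affinities[status == CLONAL], threshold_nm, unit)


def neoantigen_profiles(
    affinities: pd.DataFrame,
    clonality: Mapping[str, str] | None = None,
    unit: str = "peptide",
) -> list[NeoantigenProfile]:
    """Per-patient candidate burdens at the 500 and 50 nM thresholds."""
    out = []
    for pid, grp in affinities.groupby("patient_id", sort=True):
        out.append(NeoantigenProfile(
            patient_id=str(pid),
            n_candidates_500=count_candidates(grp, 500.0, unit),
            n_candidates_50=count_candidates(grp, 50.0, unit),
            n_clonal_candidates_500=(
                None if clonality is None
                else clonal_neoantigen_burden(grp, clonality, 500.0, unit)
            ),
        ))
    return out


def profiles_to_frame(profiles: Sequence[NeoantigenProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": p.patient_id,
        "n_candidates_500": p.n_candidates_500,
        "n_candidates_50": p.n_candidates_50,
        "n_clonal_candidates_500": p.n_clonal_candidates_500,
    } for p in profiles])
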
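"""Tumor mutation burden metrics, reference percentile ranks, stratification.

TMB here is an absolute variant count per tumor exome (the unit the study
design uses: "mutations"), not a per-megabase rate; no capture-size
normalization is applied. Panel-restricted counts estimate exome TMB from the
genes on a targeted sequencing panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGroupingError, ParameterError, ValidationError
from .io import GenePanel, VariantRecord

SCHEMES = ("nonsynonymous", "all")


@dataclass(frozen=True)
class TMBProfile:
    """Per-patient mutation-burden metrics."""

    patient_id: str
    tmb_nonsyn: int
    tmb_total: int
    tmb_by_panel: Mapping[str, int]
    percentile_rank: float | None = None


@dataclass(frozen=True)
class ReferenceCohort:
    """A reference TMB distribution with a recorded histology mix."""

    entries: tuple[tuple[str, str, int], ...]  # (sample_id, histology, tmb)
    squamous_fraction: float

    @property
    def tmbs(self) -> np.ndarray:
        return np.array([t for _, _, t in self.entries])


def _check_single_patient(variants: Sequence[VariantRecord]) -> None:
    patients = {v.patient_id for v in variants}
    if len(patients) > 1:
        raise ValidationError(f"variants span multiple patients: {sorted(patients)}")


def compute_tmb(variants: Sequence[VariantRecord], scheme: str = "nonsynonymous") -> int:
    """Count a patient's (post-filter) variants under a counting scheme.

    ``nonsynonymous`` counts SNVs and indels whose effect class is
    nonsynonymous — the TMB definition proper. ``all`` counts every variant,
    silent ones included.
    """
    if scheme not in SCHEMES:
        raise ParameterError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    _check_single_patient(variants)
    if scheme == "all":
        return len(variants)
    return sum(1 for v in variants if v.effect_class == "nonsynonymous")


def panel_restricted_tmb(
    variants: Sequence[VariantRecord],
    panel: GenePanel,
    scheme: str = "nonsynonymous",
) -> int:
    """TMB restricted to variants in genes covered by a targeted panel."""
    if not panel.genes:
        raise ParameterError(f"panel {panel.name!r} is empty")
    subset = [v for v in variants if v.gene in panel.genes]
    return compute_tmb(subset, scheme=scheme)


def build_reference_cohort(
    adeno_tmbs: Sequence[int],
    squamous_pool: Sequence[int],
    n_squamous: int,
    seed: int,
) -> ReferenceCohort:
    """Assemble a mixed-histology reference cohort.

    All adenocarcinoma samples are kept; ``n_squamous`` squamous samples are
    drawn uniformly at random (seeded, without replacement) from the pool, to
    hit a target histologic mix (e.g. 80/20).
    """
    if n_squamous > len(squamous_pool):
        raise ParameterError(
            f"n_squamous={n_squamous} exceeds squamous pool size {len(squamous_pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(squamous_pool), size=n_squamous, replace=False)
    entries = [(f"adeno{i}", "adeno", int(t)) for i, t in enumerate(adeno_tmbs)]
    entries += [(f"squam{j}", "squamous", int(squamous_pool[j])) for j in sorted(idx)]
    if not entries:
        raise ParameterError("reference cohort would be empty")
    return ReferenceCohort(
        entries=tuple(entries),
        squamous_fraction=n_squamous / len(entries),
    )


def percentile_rank(tmb: float, reference: ReferenceCohort) -> float:
    """Percentile rank of a TMB value within the reference cohort (0-100).

    Midrank convention: ties contribute half, i.e.
    ``100 * (#strictly below + 0.5 * #equal) / N``. This makes the rank stable
    under ties and monotone in TMB.
    """
    ref = reference.tmbs
    if ref.size == 0:
        raise ParameterError("empty reference cohort")
    below = np.count_nonzero(ref < tmb)
    ties = np.count_nonzero(ref == tmb)
    return 100.0 * (below + 0.5 * ties) / ref.size


@dataclass(frozen=True)
class Stratification:
    labels: tuple[str, ...]
    cut_points: tuple[float, ...]
    rule: str


def stratify(
    values: Sequence[float],
    rule: str = "median_split",
    threshold: float | None = None,
) -> Stratification:
    """Assign each patient a group label from a metric.

    ``median_split`` labels "high" iff value > median (strict; ties go low).
    ``tertiles`` / ``quartiles`` label T1..T3 / Q1..Q4 using half-open
    inclusive-lower bins at the empirical quantile cut points (top bin closed).
    ``threshold`` labels "high" iff value > the explicit threshold.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ParameterError("need at least two patients to stratify")
    if rule == "threshold":
        if threshold is None:
            raise ParameterError("explicit threshold rule requires a threshold")
        cuts = (float(threshold),)
        labels = tuple("high" if v > threshold else "low" for v in vals)
    elif rule == "median_split":
        med = float(np.median(vals))
        cuts = (med,)
        labels = tuple("high" if v > med else "low" for v in vals)
    elif rule in ("tertiles", "quartiles"):
        k = 3 if rule == "tertiles" else 4
        qs = np.quantile(vals, np.linspace(0, 1, k + 1)[1:-1])
        if np.unique(vals).size == 1:
            raise DegenerateGroupingError("all values equal; quantile rule degenerate")
        prefix = "T" if k == 3 else "Q"
        # half-open bins [cut_i, cut_{i+1}); searchsorted(side='right') puts a
        # value equal to a cut point into the upper bin, top bin inclusive
        bins = np.searchsorted(qs, vals, side="right")
        labels = tuple(f"{prefix}{b + 1}" for b in bins)
        cuts = tuple(float(q) for q in qs)
    else:
        raise ParameterError(f"unknown stratification rule {rule!r}")
    return Stratification(labels=labels, cut_points=cuts, rule=rule)


def compute_profiles(
    variants_by_patient: Mapping[str, Sequence[VariantRecord]],
    panels: Iterable[GenePanel] = (),
    reference: ReferenceCohort | None = None,
) -> list[TMBProfile]:
    """Build the full TMB profile for each patient."""
    panels = list(panels)
    out = []
    for pid, variants in variants_by_patient.items():
        nonsyn = compute_tmb(variants, "nonsynonymous")
        out.append(TMBProfile(
            patient_id=pid,
            tmb_nonsyn=nonsyn,
            tmb_total=compute_tmb(variants, "all"),
            tmb_by_panel={p.name: panel_restricted_tmb(variants, p) for p in panels},
            percentile_rank=(
                percentile_rank(nonsyn, reference) if reference is not None else None
            ),
        ))
    return out


def profiles_to_frame(profiles: Sequence[TMBProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "patient_id": p.patient_id,
            "tmb_nonsyn": p.tmb_nonsyn,
            "tmb_total": p.tmb_total,
            "percentile_rank": p.percentile_rank,
        }
        for name, count in p.tmb_by_panel.items():
            row[f"tmb_{name}"] = count
        rows.append(row)
    return pd.DataFrame(rows)
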
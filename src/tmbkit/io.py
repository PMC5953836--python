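"""Cohort ingest: variant, clinical, panel, HLA, and peptide-affinity tables.

All downstream stages consume the validated records produced here. The variant
dialect is MAF-like: tab-separated, 1-based inclusive coordinates, one variant
per row. Column names follow the documented defaults but can be remapped via
``column_map`` because public MAF exports vary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import FormatError, ParameterError, ValidationError

EFFECT_CLASSES = ("nonsynonymous", "synonymous", "other")

VARIANT_COLUMNS = (
    "patient_id", "chrom", "pos", "ref", "alt", "gene",
    "consequence", "t_alt_count", "t_depth",
)

_RESPONSES = ("CR", "PR", "SD", "PD", "NE")


def default_effect_map() -> dict[str, str]:
    """Consequence-term -> effect-class mapping shipped with the package."""
    text = (importlib.resources.files("tmbkit") / "data" / "effect_classes.yaml").read_text()
    return _parse_effect_map(yaml.safe_load(text))


def load_effect_map(path) -> dict[str, str]:
    """Load a consequence vocabulary map from a YAML file.

    The file holds one list of consequence terms per effect class; the
    returned dict maps each normalized term to its class.
    """
    return _parse_effect_map(yaml.safe_load(Path(path).read_text()))


def _parse_effect_map(raw: Mapping) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for cls, terms in raw.items():
        if cls not in EFFECT_CLASSES:
            raise FormatError(f"unknown effect class {cls!r} in vocabulary map")
        mapping[cls] = cls  # already-normalized tables map to themselves
        for term in terms:
            mapping[_norm_term(str(term))] = cls
    return mapping


def _norm_term(term: str) -> str:
    return term.strip().lower().replace(" ", "_")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with read support, effect class, and gene."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect_class: str       # one of EFFECT_CLASSES
    variant_type: str       # "SNV" iff single-base ref and alt, else "indel"
    alt_count: int
    depth: int
    vaf: float
    excluded: bool = False  # optional site-artifact exclusion flag

    def __post_init__(self):
        if not (0 <= self.alt_count <= self.depth):
            raise ValidationError(
                f"variant {self.key}: alt_count {self.alt_count} outside "
                f"[0, depth={self.depth}]"
            )
        if self.depth > 0:
            expected = self.alt_count / self.depth
            if abs(self.vaf - expected) > 1e-9:
                raise ValidationError(
                    f"variant {self.key}: vaf {self.vaf} != alt_count/depth"
                )
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect_class {self.effect_class!r}")
        expected_type = "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        if self.variant_type != expected_type:
            raise ValidationError(
                f"variant {self.key}: variant_type {self.variant_type!r} "
                f"inconsistent with alleles"
            )

    @property
    def key(self) -> str:
        """Stable mutation key: chrom:pos:ref>alt."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and outcomes for one patient."""

    patient_id: str
    best_response: str               # CR / PR / SD / PD / NE
    dcb: bool                        # durable clinical benefit (>6 mo PR/SD)
    pfs_months: float
    pfs_event: bool
    pd_l1_pct: float | None          # percent tumor cells staining; None = unknown
    histology: str                   # squamous / non-squamous
    smoking: str                     # ever / never
    ecog: int                        # 0 / 1
    hla_alleles: frozenset[str] = frozenset()
    tumor_mean_cov: float | None = None
    normal_mean_cov: float | None = None

    def __post_init__(self):
        if self.best_response not in _RESPONSES:
            raise ValidationError(
                f"patient {self.patient_id}: best_response {self.best_response!r}"
            )
        if self.pfs_months < 0:
            raise ValidationError(f"patient {self.patient_id}: negative pfs_months")
        if self.pd_l1_pct is not None and not (0 <= self.pd_l1_pct <= 100):
            raise ValidationError(f"patient {self.patient_id}: pd_l1_pct out of range")
        if len(self.hla_alleles) > 6:
            raise ValidationError(f"patient {self.patient_id}: >6 class-I HLA alleles")
        if self.ecog not in (0, 1):
            raise ValidationError(f"patient {self.patient_id}: ecog must be 0 or 1")

    @property
    def responder(self) -> bool:
        """Objective responder: confirmed complete or partial response."""
        return self.best_response in ("CR", "PR")


@dataclass(frozen=True)
class GenePanel:
    """A named targeted-sequencing gene panel."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"panel {self.name!r} is empty")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_variant_table(
    path,
    effect_map: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a MAF-like TSV of somatic variants into validated records.

    ``vaf`` is computed from ``t_alt_count / t_depth`` when absent. The
    ``consequence`` column is normalized into the three effect classes via
    ``effect_map`` (package default used when None); unrecognized terms fall
    into class ``other``. An optional boolean ``exclude_flag`` column marks
    site-artifact exclusions applied later by :func:`apply_variant_filters`.
    """
    if effect_map is None:
        effect_map = default_effect_map()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            alt_count = int(row.t_alt_count)
            depth = int(row.t_depth)
        except ValueError as exc:
            raise FormatError(f"{path} line {i}: non-integer read counts") from exc
        if alt_count > depth:
            raise ValidationError(
                f"{path} line {i}: t_alt_count {alt_count} > t_depth {depth}"
            )
        if getattr(row, "vaf", "") != "":
            vaf = float(row.vaf)
        else:
            vaf = alt_count / depth if depth > 0 else 0.0
        ref, alt = str(row.ref), str(row.alt)
        records.append(VariantRecord(
            patient_id=str(row.patient_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=ref,
            alt=alt,
            gene=str(row.gene),
            effect_class=effect_map.get(_norm_term(str(row.consequence)), "other"),
            variant_type="SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
            alt_count=alt_count,
            depth=depth,
            vaf=vaf,
            excluded=_parse_bool(getattr(row, "exclude_flag", "")),
        ))
    return records


def _parse_bool(v: str) -> bool:
    return str(v).strip().lower() in ("1", "true", "yes")


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records in the exact dialect :func:`read_variant_table` reads.

    The consequence column carries the (already normalized) effect class, so a
    write/read round trip reproduces identical records.
    """
    rows = [{
        "patient_id": r.patient_id, "chrom": r.chrom, "pos": r.pos,
        "ref": r.ref, "alt": r.alt, "gene": r.gene,
        "consequence": r.effect_class, "t_alt_count": r.alt_count,
        "t_depth": r.depth, "vaf": repr(r.vaf),
        "exclude_flag": int(r.excluded),
    } for r in records]
    pd.DataFrame(rows, columns=[
        "patient_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
        "t_alt_count", "t_depth", "vaf", "exclude_flag",
    ]).to_csv(path, sep="\t", index=False)


def apply_variant_filters(
    variants: Sequence[VariantRecord],
    min_vaf: float = 0.05,
    drop_flagged: bool = True,
) -> list[VariantRecord]:
    """Exclude variants with VAF strictly below ``min_vaf``.

    The boundary (VAF exactly ``min_vaf``) is retained: the exclusion rule is
    strictly "VAF < threshold". Records carrying the site-artifact exclusion
    flag are also dropped unless ``drop_flagged`` is False. Order is
    preserved and the input is not modified.
    """
    if not (0 <= min_vaf <= 1):
        raise ParameterError(f"min_vaf must lie in [0, 1], got {min_vaf}")
    return [
        v for v in variants
        if v.vaf >= min_vaf and not (drop_flagged and v.excluded)
    ]


def qc_sample(
    patient: PatientRecord,
    tumor_min: float = 60.0,
    normal_min: float = 30.0,
) -> QCResult:
    """Coverage QC: fail a sample with mean target coverage below threshold.

    Exclusion is strict "<": a tumor at exactly 60X and normal at 30X passes.
    """
    if patient.tumor_mean_cov is None or patient.normal_mean_cov is None:
        raise ValidationError(f"patient {patient.patient_id}: coverage missing")
    if patient.tumor_mean_cov < 0 or patient.normal_mean_cov < 0:
        raise ValidationError(f"patient {patient.patient_id}: negative coverage")
    reasons = []
    if patient.tumor_mean_cov < tumor_min:
        reasons.append(f"tumor coverage {patient.tumor_mean_cov:g}X < {tumor_min:g}X")
    if patient.normal_mean_cov < normal_min:
        reasons.append(f"normal coverage {patient.normal_mean_cov:g}X < {normal_min:g}X")
    if reasons:
        return QCResult(False, "; ".join(reasons))
    return QCResult(True)


def read_clinical_table(path) -> list[PatientRecord]:
    """Read the per-patient clinical CSV (columns mirror PatientRecord)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "best_response", "dcb", "pfs_months", "pfs_event",
                "pd_l1_pct", "histology", "smoking", "ecog"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        pd_l1 = getattr(row, "pd_l1_pct")
        out.append(PatientRecord(
            patient_id=str(row.patient_id),
            best_response=str(row.best_response),
            dcb=bool(row.dcb),
            pfs_months=float(row.pfs_months),
            pfs_event=bool(row.pfs_event),
            pd_l1_pct=None if pd.isna(pd_l1) else float(pd_l1),
            histology=str(row.histology),
            smoking=str(row.smoking),
            ecog=int(row.ecog),
            tumor_mean_cov=_opt_float(getattr(row, "tumor_mean_cov", None)),
            normal_mean_cov=_opt_float(getattr(row, "normal_mean_cov", None)),
        ))
    return out


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def write_clinical_table(patients: Iterable[PatientRecord], path) -> None:
    rows = [{
        "patient_id": p.patient_id, "best_response": p.best_response,
        "dcb": int(p.dcb), "pfs_months": p.pfs_months,
        "pfs_event": int(p.pfs_event),
        "pd_l1_pct": "" if p.pd_l1_pct is None else p.pd_l1_pct,
        "histology": p.histology, "smoking": p.smoking, "ecog": p.ecog,
        "tumor_mean_cov": "" if p.tumor_mean_cov is None else p.tumor_mean_cov,
        "normal_mean_cov": "" if p.normal_mean_cov is None else p.normal_mean_cov,
    } for p in patients]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gene_panel(path, name: str | None = None) -> GenePanel:
    """Read a gene panel: one symbol per line, '#' starts a comment."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return GenePanel(name=name or Path(path).stem, genes=frozenset(genes))


def read_hla_table(path) -> dict[str, frozenset[str]]:
    """Read patient -> class-I HLA alleles (TSV: patient_id, allele)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"patient_id", "allele"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns patient_id, allele")
    out: dict[str, frozenset[str]] = {}
    for pid, grp in df.groupby("patient_id"):
        alleles = frozenset(grp["allele"])
        if len(alleles) > 6:
            raise ValidationError(f"patient {pid}: >6 class-I alleles")
        out[str(pid)] = alleles
    return out


AFFINITY_COLUMNS = ("patient_id", "mutation_key", "peptide", "allele", "ic50_nm")


def read_affinity_table(path) -> pd.DataFrame:
    """Read the precomputed peptide-MHC affinity TSV.

    Affinities are produced upstream by an external binding predictor; this
    package only consumes them. Returns a validated DataFrame with the
    canonical columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    lengths = df["peptide"].str.len()
    bad = df[(lengths < 8) | (lengths > 11)]
    if len(bad):
        raise ValidationError(
            f"{path}: {len(bad)} peptide(s) outside the 8-11mer range"
        )
    if (df["ic50_nm"] <= 0).any():
        raise ValidationError(f"{path}: non-positive IC50 values")
    return df[list(AFFINITY_COLUMNS)].copy()


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabular view of variant records (one row per variant)."""
    return pd.DataFrame([{
        "patient_id": r.patient_id, "mutation_key": r.key, "chrom": r.chrom,
        "pos": r.pos, "ref": r.ref, "alt": r.alt, "gene": r.gene,
        "effect_class": r.effect_class, "variant_type": r.variant_type,
        "alt_count": r.alt_count, "depth": r.depth, "vaf": r.vaf,
        "excluded": r.excluded,
    } for r in records])
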
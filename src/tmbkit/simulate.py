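"""Synthetic immunotherapy-cohort generator.

Generates complete study datasets — clinical table, variant tables with read
counts / purity / copy number, HLA lists, peptide-affinity tables, gene
panels, and a reference cohort — with the statistical structure the analysis
assumes, so every stage is testable without any external download:

* TMB is log-normal within response class, with responder / non-responder
  medians of 273 and 114 mutations and a common log-scale spread.
* PD-L1 expression is drawn independently of TMB (point mass at 0%, else
  uniform 1-100%), so their correlation is ~0 by construction.
* PFS is exponential within TMB group. The printed group medians (17.1 / 3.7
  months) and hazard ratio (0.41) are mutually inconsistent under
  exponential survival, so ``pfs_mode`` selects which to match; the default
  matches the hazard ratio with the low-TMB median anchored at 3.7 months,
  the hazard ratio being the headline statistic.
* Reads follow the clonality forward model: depth ~ Poisson(148), alt reads
  ~ Binomial(depth, expected VAF at the variant's true CCF); clonal variants
  have CCF 1, subclonal CCF ~ Uniform(0.1, 0.6).
* Per nonsynonymous variant, all 8-11mer windows containing the mutated
  residue get an IC50 drawn log-uniformly, which yields a per-patient
  candidate burden proportional to TMB (binomial thinning), emulating the
  tight burden/TMB correlation seen in real cohorts.

Every latent quantity (true TMB, true CCF and clonality, sub-threshold VAF
drops) is recorded in a truth block that analysis stages never read.
"""

from __future__ import annotations

import dataclasses
import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .neoantigen import enumerate_mutant_peptides
from .tmb import ReferenceCohort, build_reference_cohort

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# common class-I alleles used as the synthetic allele pool (A/B/C loci)
_HLA_POOL = {
    "A": ["A*01:01", "A*02:01", "A*03:01", "A*11:01", "A*24:02", "A*26:01"],
    "B": ["B*07:02", "B*08:01", "B*15:01", "B*35:01", "B*44:02", "B*44:03"],
    "C": ["C*03:04", "C*04:01", "C*05:01", "C*06:02", "C*07:01", "C*07:02"],
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for cohort generation.

    Defaults reproduce the target cohort: 75 patients, objective response
    rate 0.32, response-class TMB medians 273 / 114 with log-sd 0.9 (chosen
    so the asymptotic TMB-response AUC is ~0.75), DCB rates 0.65 / 0.34 by
    TMB group, PFS medians 17.1 / 3.7 months or hazard ratio 0.41 depending
    on ``pfs_mode``, mean tumor depth 148X, and targeted panels of 468 and
    315 genes.
    """

    n_patients: int = 75
    orr: float = 0.32
    tmb_median_responder: float = 273.0
    tmb_median_nonresponder: float = 114.0
    tmb_log_sd: float = 0.9
    silent_fraction: float = 0.25
    pd_l1_zero_fraction: float = 0.33
    pd_l1_missing_fraction: float = 5 / 75
    dcb_rate_tmb_high: float = 0.65
    dcb_rate_tmb_low: float = 0.34
    pfs_mode: str = "match_hr"          # or "match_medians"
    pfs_median_high: float = 17.1
    pfs_median_low: float = 3.7
    target_hr: float = 0.41
    censor_window: float = 30.0         # months of administrative follow-up
    clonal_fraction: float = 0.8
    purity_range: tuple[float, float] = (0.2, 0.9)
    depth_mean: float = 148.0
    indel_fraction: float = 0.1         # of nonsynonymous variants
    squamous_fraction: float = 0.21
    smoker_fraction: float = 0.80
    ecog0_fraction: float = 0.40
    min_vaf: float = 0.05               # sub-threshold variants are dropped
    panel_sizes: tuple[int, ...] = (468, 315)
    gene_universe_size: int = 19000
    peptide_ic50_log_range: tuple[float, float] = (0.0, 4.7)  # log10 nM
    generate_affinities: bool = True
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "orr": self.orr, "silent_fraction": self.silent_fraction,
            "pd_l1_zero_fraction": self.pd_l1_zero_fraction,
            "pd_l1_missing_fraction": self.pd_l1_missing_fraction,
            "dcb_rate_tmb_high": self.dcb_rate_tmb_high,
            "dcb_rate_tmb_low": self.dcb_rate_tmb_low,
            "clonal_fraction": self.clonal_fraction,
            "indel_fraction": self.indel_fraction,
            "squamous_fraction": self.squamous_fraction,
            "smoker_fraction": self.smoker_fraction,
            "ecog0_fraction": self.ecog0_fraction,
            "min_vaf": self.min_vaf,
        }
        for name, v in fractions.items():
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("tmb_median_responder", "tmb_median_nonresponder",
                     "pfs_median_high", "pfs_median_low", "target_hr",
                     "depth_mean", "censor_window"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.pfs_mode not in ("match_hr", "match_medians"):
            raise ParameterError(f"unknown pfs_mode {self.pfs_mode!r}")
        if not (0 < self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ParameterError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.n_patients < 2:
            raise ParameterError("need at least 2 patients")
        if self.seed is None:
            raise ParameterError("seed is mandatory")


@dataclass
class SyntheticDataset:
    """All generated tables plus the latent truth record."""

    clinical: pd.DataFrame
    variants: pd.DataFrame
    ccf_inputs: pd.DataFrame
    hla: pd.DataFrame
    affinities: pd.DataFrame | None
    panels: Mapping[str, frozenset]
    reference: ReferenceCohort
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def _gene_universe(size: int) -> np.ndarray:
    letters = string.ascii_uppercase
    return np.array([
        f"G{letters[i % 26]}{i:05d}" for i in range(size)
    ])


def _random_peptides(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    total = int(lengths.sum())
    flat = rng.integers(0, len(_AMINO_ACIDS), size=total)
    chars = _AMINO_ACIDS[flat]
    out = []
    pos = 0
    for ln in lengths:
        out.append("".join(chars[pos:pos + ln]))
        pos += ln
    return out


def generate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study dataset.

    Deterministic given the config (one seeded generator drives everything):
    the same config produces a byte-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i + 1:04d}" for i in range(n)]

    # --- response class and true TMB ------------------------------------
    responder = rng.random(n) < config.orr
    mu = np.where(responder,
                  math.log(config.tmb_median_responder),
                  math.log(config.tmb_median_nonresponder))
    true_tmb = np.maximum(
        1, np.round(np.exp(rng.normal(mu, config.tmb_log_sd))).astype(int)
    )
    best_response = np.where(
        responder,
        rng.choice(["CR", "PR"], size=n, p=[0.1, 0.9]),
        rng.choice(["SD", "PD", "NE"], size=n, p=[0.5, 0.45, 0.05]),
    )

    # --- PD-L1 independent of TMB ---------------------------------------
    pd_l1 = np.where(rng.random(n) < config.pd_l1_zero_fraction,
                     0.0, rng.uniform(1.0, 100.0, size=n))
    pd_l1 = pd_l1.astype(object)
    missing = rng.random(n) < config.pd_l1_missing_fraction
    pd_l1[missing] = None

    # --- TMB group, DCB, PFS --------------------------------------------
    tmb_median = np.median(true_tmb)
    tmb_high = true_tmb > tmb_median
    dcb = rng.random(n) < np.where(tmb_high, config.dcb_rate_tmb_high,
                                   config.dcb_rate_tmb_low)
    rate_low = math.log(2) / config.pfs_median_low
    if config.pfs_mode == "match_hr":
        rate_high = config.target_hr * rate_low
    else:
        rate_high = math.log(2) / config.pfs_median_high
    pfs_true = rng.exponential(1.0 / np.where(tmb_high, rate_high, rate_low))
    pfs_event = pfs_true <= config.censor_window
    pfs_months = np.minimum(pfs_true, config.censor_window)

    # --- other covariates ------------------------------------------------
    histology = np.where(rng.random(n) < config.squamous_fraction,
                         "squamous", "non-squamous")
    smoking = np.where(rng.random(n) < config.smoker_fraction, "ever", "never")
    ecog = np.where(rng.random(n) < config.ecog0_fraction, 0, 1)
    tumor_cov = np.maximum(60.0, rng.normal(config.depth_mean, 40.0, size=n))
    normal_cov = np.maximum(30.0, rng.normal(81.0, 20.0, size=n))
    purity = rng.uniform(*config.purity_range, size=n)

    clinical = pd.DataFrame({
        "patient_id": pids,
        "best_response": best_response,
        "dcb": dcb.astype(int),
        "pfs_months": np.round(pfs_months, 3),
        "pfs_event": pfs_event.astype(int),
        "pd_l1_pct": [None if v is None else round(float(v), 1) for v in pd_l1],
        "histology": histology,
        "smoking": smoking,
        "ecog": ecog,
        "tumor_mean_cov": np.round(tumor_cov, 1),
        "normal_mean_cov": np.round(normal_cov, 1),
    })

    # --- HLA table -------------------------------------------------------
    hla_rows = []
    for pid in pids:
        alleles = set()
        for locus_pool in _HLA_POOL.values():
            alleles.update(rng.choice(locus_pool, size=2, replace=True))
        for allele in sorted(alleles):
            hla_rows.append({"patient_id": pid, "allele": allele})
    hla = pd.DataFrame(hla_rows)

    # --- gene universe and panels ---------------------------------------
    universe = _gene_universe(config.gene_universe_size)
    panels = {}
    for size in config.panel_sizes:
        idx = rng.choice(len(universe), size=size, replace=False)
        panels[f"panel_{size}"] = frozenset(universe[np.sort(idx)])

    # --- variants (vectorized across the whole cohort) -------------------
    n_nonsyn = true_tmb
    n_total = np.round(n_nonsyn / (1.0 - config.silent_fraction)).astype(int)
    n_silent = n_total - n_nonsyn
    counts = n_total
    pid_idx = np.repeat(np.arange(n), counts)
    m = int(counts.sum())
    is_nonsyn = np.zeros(m, dtype=bool)
    offset = 0
    for i in range(n):
        is_nonsyn[offset:offset + n_nonsyn[i]] = True
        offset += counts[i]

    is_indel = is_nonsyn & (rng.random(m) < config.indel_fraction)
    consequence = np.where(
        ~is_nonsyn, "silent",
        np.where(is_indel, "frameshift",
                 np.where(rng.random(m) < 0.9, "missense", "nonsense")),
    )
    clonal = rng.random(m) < config.clonal_fraction
    true_ccf = np.where(clonal, 1.0, rng.uniform(0.1, 0.6, size=m))
    pur = purity[pid_idx]
    exp_vaf = (pur * true_ccf) / (2.0 * (1.0 - pur) + pur * 2.0)
    depth = np.maximum(1, rng.poisson(config.depth_mean, size=m))
    alt = rng.binomial(depth, exp_vaf)
    vaf = alt / depth

    genes = universe[rng.integers(0, len(universe), size=m)]
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 23, size=m)])
    pos = rng.integers(1, 250_000_000, size=m)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    alt_base = bases[(np.searchsorted(bases, ref) + shift) % 4]
    # indels get a multi-base ref allele so variant_type is derivable
    ins = rng.integers(0, 4, size=m)
    ref = np.where(is_indel, np.char.add(ref, bases[ins]), ref)

    variants = pd.DataFrame({
        "patient_id": np.array(pids)[pid_idx],
        "chrom": chroms,
        "pos": pos,
        "ref": ref,
        "alt": alt_base,
        "gene": genes,
        "consequence": consequence,
        "t_alt_count": alt,
        "t_depth": depth,
        "vaf": vaf,
        "exclude_flag": 0,
        "true_ccf": true_ccf,
        "true_clonal": clonal,
    })
    variants["mutation_key"] = (
        variants["chrom"] + ":" + variants["pos"].astype(str) + ":"
        + variants["ref"] + ">" + variants["alt"]
    )

    kept = variants["vaf"] >= config.min_vaf
    n_dropped = int((~kept).sum())
    emitted = variants[kept].reset_index(drop=True)

    truth = {
        "per_patient": pd.DataFrame({
            "patient_id": pids,
            "responder": responder.astype(int),
            "true_tmb_nonsyn": true_tmb,
            "true_tmb_total": n_total,
            "tmb_high": tmb_high.astype(int),
            "purity": np.round(purity, 4),
            "pfs_uncensored": np.round(pfs_true, 3),
        }),
        "per_variant": variants[["patient_id", "mutation_key", "true_ccf",
                                 "true_clonal", "vaf"]].copy(),
        "n_dropped_low_vaf": n_dropped,
    }

    purity_by_pid = dict(zip(pids, np.round(purity, 4)))
    snv = emitted[emitted["ref"].str.len().eq(1) & emitted["alt"].str.len().eq(1)]
    ccf_inputs = pd.DataFrame({
        "patient_id": snv["patient_id"],
        "mutation_key": snv["mutation_key"],
        "alt_count": snv["t_alt_count"],
        "depth": snv["t_depth"],
        "purity": snv["patient_id"].map(purity_by_pid),
        "cpn_normal": 2,
        "cpn_tumor_mut": 2,
        "variant_type": "SNV",
    }).reset_index(drop=True)

    affinities = None
    if config.generate_affinities:
        affinities = _generate_affinities(rng, emitted, hla, config)

    # --- reference cohort ------------------------------------------------
    ref_adeno, ref_squam = generate_reference_tmbs(seed=int(rng.integers(2**31)))
    reference = build_reference_cohort(ref_adeno, ref_squam, n_squamous=141,
                                       seed=int(rng.integers(2**31)))

    emitted = emitted.drop(columns=["true_ccf", "true_clonal"])
    return SyntheticDataset(
        clinical=clinical, variants=emitted, ccf_inputs=ccf_inputs, hla=hla,
        affinities=affinities, panels=panels, reference=reference,
        truth=truth, config=config,
    )


def _generate_affinities(rng, emitted: pd.DataFrame, hla: pd.DataFrame,
                         config: SimulationConfig) -> pd.DataFrame:
    """Window enumeration + log-uniform IC50 draws for nonsynonymous variants."""
    alleles_by_patient = {
        pid: list(grp["allele"]) for pid, grp in hla.groupby("patient_id")
    }
    nonsyn = emitted[emitted["consequence"] != "silent"]
    pid_list, key_list, len_list = [], [], []
    for row in nonsyn.itertuples(index=False):
        protein_length = int(rng.integers(100, 1000))
        position = int(rng.integers(1, protein_length + 1))
        multi = len(row.ref) > 1
        windows = enumerate_mutant_peptides(protein_length, position,
                                            multi_residue=multi)
        if multi:
            # frameshifts alter everything downstream; cap the enumeration at
            # the interior-SNV window count to keep burdens comparable
            windows = windows[:38]
        for _, length in windows:
            pid_list.append(row.patient_id)
            key_list.append(row.mutation_key)
            len_list.append(length)
    lengths = np.array(len_list, dtype=int)
    peptides = _random_peptides(rng, lengths)
    lo, hi = config.peptide_ic50_log_range
    ic50 = 10.0 ** rng.uniform(lo, hi, size=len(peptides))
    allele_choice = [
        alleles_by_patient[pid][rng.integers(0, len(alleles_by_patient[pid]))]
        for pid in pid_list
    ]
    return pd.DataFrame({
        "patient_id": pid_list,
        "mutation_key": key_list,
        "peptide": peptides,
        "allele": allele_choice,
        "ic50_nm": np.round(ic50, 4),
    })


def generate_reference_tmbs(
    n_adeno: int = 569,
    n_squamous_pool: int = 491,
    adeno_median: float = 160.0,
    squamous_median: float = 210.0,
    log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Log-normal reference TMB draws per histology, for percentile ranking."""
    if n_adeno <= 0 or n_squamous_pool <= 0:
        raise ParameterError("reference sizes must be positive")
    rng = np.random.default_rng(seed)
    adeno = np.maximum(1, np.round(
        np.exp(rng.normal(math.log(adeno_median), log_sd, size=n_adeno))
    ).astype(int))
    squam = np.maximum(1, np.round(
        np.exp(rng.normal(math.log(squamous_median), log_sd, size=n_squamous_pool))
    ).astype(int))
    return adeno.tolist(), squam.tolist()


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write all tables in the exact file dialects the ingest module reads.

    The truth record is written separately (truth.json + truth_*.tsv) and is
    never read by any analysis stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.clinical.to_csv(outdir / "clinical.csv", index=False)
    cols = ["patient_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
            "t_alt_count", "t_depth", "vaf", "exclude_flag"]
    dataset.variants[cols].to_csv(outdir / "variants.tsv", sep="\t", index=False)
    dataset.ccf_inputs.to_csv(outdir / "ccf_inputs.tsv", sep="\t", index=False)
    dataset.hla.to_csv(outdir / "hla.tsv", sep="\t", index=False)
    if dataset.affinities is not None:
        dataset.affinities.to_csv(outdir / "affinities.tsv", sep="\t", index=False)
    for name, genes in dataset.panels.items():
        (outdir / f"{name}.txt").write_text(
            "# synthetic gene panel\n" + "\n".join(sorted(genes)) + "\n"
        )
    ref_rows = pd.DataFrame(dataset.reference.entries,
                            columns=["sample_id", "histology", "tmb"])
    ref_rows.to_csv(outdir / "reference_cohort.tsv", sep="\t", index=False)
    dataset.truth["per_patient"].to_csv(outdir / "truth_patients.tsv",
                                        sep="\t", index=False)
    dataset.truth["per_variant"].to_csv(outdir / "truth_variants.tsv",
                                        sep="\t", index=False)
    meta = {
        "n_dropped_low_vaf": dataset.truth["n_dropped_low_vaf"],
        "config": dataclasses.asdict(dataset.config) if dataset.config else None,
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=2, default=list))
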
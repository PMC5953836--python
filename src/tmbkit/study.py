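"""End-to-end cohort analysis.

:class:`CohortStudy` bundles the validated inputs (clinical table, variants,
panels, reference cohort, CCF inputs, affinities); ``fit()`` runs the stages
in dependency order — QC / VAF filtering, TMB and percentile ranks, clonality,
neoantigen burdens, and the association statistics — and returns a
:class:`StudyResults` object whose blocks mirror the study's analyses:
cohort summary, TMB-by-outcome, percentile/quartile survival, composite
TMB x PD-L1, per-gene scan, and multivariable adjustment. Each block is
either populated or explicitly marked skipped with a reason; a stage failure
aborts with an error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import clonality as cl
from . import io as cio
from . import neoantigen as neo
from . import stats as st
from . import tmb as tq
from .errors import StageError, TmbkitError
from .simulate import SimulationConfig, SyntheticDataset, generate_cohort

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, st.AssociationResult):
        return obj.as_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class StudyResults:
    """Analysis report: one entry per block, plus provenance."""

    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def block(self, name: str):
        return self.blocks[name]

    def skipped(self, name: str) -> bool:
        b = self.blocks.get(name)
        return isinstance(b, dict) and "skipped" in b

    def to_json(self, indent: int = 2) -> str:
        payload = {"blocks": _jsonable(self.blocks),
                   "provenance": _jsonable(self.provenance)}
        return json.dumps(payload, indent=indent, sort_keys=True, default=str)

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def summary(self) -> str:
        """Human-readable digest of the headline statistics."""
        lines = [f"CohortStudy results (tmbkit {self.provenance.get('version')})"]
        cs = self.blocks.get("cohort_summary", {})
        if cs and "skipped" not in cs:
            lines.append(
                f"  patients: {cs['n_patients']} "
                f"(TMB-high {cs['n_tmb_high']} / TMB-low {cs['n_tmb_low']}, "
                f"median TMB {cs['tmb_median']:g})"
            )
        tb = self.blocks.get("tmb_by_outcome", {})
        if tb and "skipped" not in tb:
            orr = tb["orr_by_tmb_group"]
            lines.append(
                f"  ORR high vs low TMB: {tb['orr_high_pct']:.0f}% vs "
                f"{tb['orr_low_pct']:.0f}% (OR {orr.effect:.2f}, p {orr.p_value:.2g})"
            )
            dcb = tb["dcb_by_tmb_group"]
            lines.append(
                f"  DCB high vs low TMB: {tb['dcb_high_pct']:.0f}% vs "
                f"{tb['dcb_low_pct']:.0f}% (OR {dcb.effect:.2f}, p {dcb.p_value:.2g})"
            )
            lines.append(
                f"  TMB responder vs non-responder: median "
                f"{tb['tmb_median_responder']:g} vs {tb['tmb_median_nonresponder']:g} "
                f"(Mann-Whitney p {tb['tmb_mw_response'].p_value:.2g}); "
                f"ROC AUC {tb['auc_response'].effect:.2f}"
            )
        sv = self.blocks.get("survival", {})
        if sv and "skipped" not in sv:
            hr = sv["pfs_by_tmb_group"]
            lines.append(
                f"  PFS high vs low TMB: HR {hr.effect:.2f} "
                f"[{hr.ci_low:.2f}, {hr.ci_high:.2f}], log-rank p {hr.p_value:.2g}"
            )
        cp = self.blocks.get("composite", {})
        if cp:
            if "skipped" in cp:
                lines.append(f"  composite TMB x PD-L1: skipped ({cp['skipped']})")
            else:
                tr = cp["trend_test"]
                lines.append(
                    f"  composite TMB x PD-L1 trend: chi2 {tr.effect:.2f}, "
                    f"p {tr.p_value:.2g}"
                )
        for name in ("neoantigen", "gene_scan", "multivariable"):
            b = self.blocks.get(name)
            if isinstance(b, dict) and "skipped" in b:
                lines.append(f"  {name}: skipped ({b['skipped']})")
        nb = self.blocks.get("neoantigen", {})
        if nb and "skipped" not in nb:
            rho = nb["spearman_tmb_vs_candidates"]
            lines.append(
                f"  neoantigen burden vs TMB: Spearman rho {rho.effect:.2f} "
                f"(p {rho.p_value:.2g})"
            )
        return "\n".join(lines)


class CohortStudy:
    """A cohort dataset ready for analysis.

    Parameters mirror the file dialects of the ingest module; use
    :meth:`from_files` to load from disk or :meth:`from_synthetic` to run on
    a generated dataset.
    """

    def __init__(
        self,
        patients: Sequence[cio.PatientRecord],
        variants: Sequence[cio.VariantRecord],
        panels: Sequence[cio.GenePanel] = (),
        reference: tq.ReferenceCohort | None = None,
        ccf_inputs: pd.DataFrame | None = None,
        affinities: pd.DataFrame | None = None,
        config: Mapping | None = None,
    ):
        self.patients = list(patients)
        self.variants = list(variants)
        self.panels = list(panels)
        self.reference = reference
        self.ccf_inputs = ccf_inputs
        self.affinities = affinities
        self.config = dict(config or {})

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_files(cls, clinical_path, variants_path, panel_paths=(),
                   reference_path=None, hla_path=None, ccf_path=None,
                   affinity_path=None, effect_map_path=None) -> "CohortStudy":
        effect_map = (cio.load_effect_map(effect_map_path)
                      if effect_map_path else None)
        patients = cio.read_clinical_table(clinical_path)
        if hla_path:
            hla = cio.read_hla_table(hla_path)
            patients = [
                cio.PatientRecord(**{**p.__dict__,
                                     "hla_alleles": hla.get(p.patient_id, frozenset())})
                for p in patients
            ]
        variants = cio.read_variant_table(variants_path, effect_map=effect_map)
        panels = [cio.read_gene_panel(p) for p in panel_paths]
        reference = None
        if reference_path:
            ref = pd.read_csv(reference_path, sep="\t")
            entries = tuple(
                (str(r.sample_id), str(r.histology), int(r.tmb))
                for r in ref.itertuples(index=False)
            )
            squam = sum(1 for e in entries if e[1] == "squamous")
            reference = tq.ReferenceCohort(entries, squam / len(entries))
        ccf_inputs = pd.read_csv(ccf_path, sep="\t") if ccf_path else None
        affinities = cio.read_affinity_table(affinity_path) if affinity_path else None
        return cls(patients, variants, panels, reference, ccf_inputs, affinities,
                   config={"clinical_path": str(clinical_path)})

    @classmethod
    def from_synthetic(cls, config: SimulationConfig) -> "CohortStudy":
        ds = generate_cohort(config)
        return cls.from_dataset(ds)

    @classmethod
    def from_dataset(cls, ds: SyntheticDataset) -> "CohortStudy":
        hla = {pid: frozenset(grp["allele"])
               for pid, grp in ds.hla.groupby("patient_id")}
        patients = []
        for row in ds.clinical.itertuples(index=False):
            patients.append(cio.PatientRecord(
                patient_id=row.patient_id, best_response=row.best_response,
                dcb=bool(row.dcb), pfs_months=float(row.pfs_months),
                pfs_event=bool(row.pfs_event),
                pd_l1_pct=None if pd.isna(row.pd_l1_pct) else float(row.pd_l1_pct),
                histology=row.histology, smoking=row.smoking, ecog=int(row.ecog),
                hla_alleles=hla.get(row.patient_id, frozenset()),
                tumor_mean_cov=float(row.tumor_mean_cov),
                normal_mean_cov=float(row.normal_mean_cov),
            ))
        effect_map = cio.default_effect_map()
        variants = []
        for row in ds.variants.itertuples(index=False):
            variants.append(cio.VariantRecord(
                patient_id=row.patient_id, chrom=row.chrom, pos=int(row.pos),
                ref=row.ref, alt=row.alt, gene=row.gene,
                effect_class=effect_map.get(row.consequence, "other"),
                variant_type="SNV" if len(row.ref) == 1 and len(row.alt) == 1
                else "indel",
                alt_count=int(row.t_alt_count), depth=int(row.t_depth),
                vaf=float(row.vaf),
            ))
        panels = [cio.GenePanel(name, genes) for name, genes in ds.panels.items()]
        import dataclasses as _dc
        return cls(patients, variants, panels, ds.reference, ds.ccf_inputs,
                   ds.affinities,
                   config=_dc.asdict(ds.config) if ds.config else {})

    # -- analysis --------------------------------------------------------

    def fit(self, min_vaf: float = 0.05, qc: bool = True) -> StudyResults:
        """Run the full analysis and return the results object."""
        results = StudyResults()
        cfg_json = json.dumps(_jsonable(self.config), sort_keys=True, default=str)
        results.provenance = {
            "version": __version__,
            "config": self.config,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": self.config.get("seed"),
            "min_vaf": min_vaf,
        }

        # --- stage: QC + variant filtering ------------------------------
        try:
            patients = self.patients
            if qc and all(p.tumor_mean_cov is not None for p in patients):
                qc_res = {p.patient_id: cio.qc_sample(p) for p in patients}
                failed = {pid for pid, r in qc_res.items() if not r.passed}
                if failed:
                    logger.info("QC excluded %d sample(s): %s", len(failed),
                                sorted(failed))
                patients = [p for p in patients if p.patient_id not in failed]
            else:
                failed = set()
            pre = len(self.variants)
            kept_pids = {p.patient_id for p in patients}
            variants = cio.apply_variant_filters(
                [v for v in self.variants if v.patient_id in kept_pids],
                min_vaf=min_vaf,
            )
            logger.info("variant filter: %d -> %d records", pre, len(variants))
        except TmbkitError as exc:
            raise StageError("qc_filter", str(exc)) from exc

        # --- stage: TMB -------------------------------------------------
        try:
            by_patient = {p.patient_id: [] for p in patients}
            for v in variants:
                by_patient.setdefault(v.patient_id, []).append(v)
            profiles = tq.compute_profiles(by_patient, self.panels, self.reference)
            prof_df = tq.profiles_to_frame(profiles).set_index("patient_id")
            clin = pd.DataFrame([{
                "patient_id": p.patient_id,
                "responder": int(p.responder),
                "dcb": int(p.dcb),
                "pfs_months": p.pfs_months,
                "pfs_event": int(p.pfs_event),
                "pd_l1_pct": p.pd_l1_pct,
                "squamous": int(p.histology == "squamous"),
                "smoker": int(p.smoking == "ever"),
                "ecog": p.ecog,
            } for p in patients]).set_index("patient_id")
            df = clin.join(prof_df, how="inner").reset_index()
            strat = tq.stratify(df["tmb_nonsyn"], "median_split")
            df["tmb_group"] = strat.labels
            results.blocks["cohort_summary"] = {
                "n_patients": len(df),
                "n_qc_failed": len(failed),
                "n_variants_post_filter": len(variants),
                "tmb_median": float(strat.cut_points[0]),
                "n_tmb_high": int((df["tmb_group"] == "high").sum()),
                "n_tmb_low": int((df["tmb_group"] == "low").sum()),
                "orr_pct": 100.0 * df["responder"].mean(),
                "dcb_pct": 100.0 * df["dcb"].mean(),
            }
        except TmbkitError as exc:
            raise StageError("tmb", str(exc)) from exc
        self._frame = df  # analysis table, exposed for downstream use

        # --- stage: TMB-by-outcome statistics ---------------------------
        try:
            results.blocks["tmb_by_outcome"] = self._tmb_by_outcome(df)
        except (TmbkitError, ValueError) as exc:
            results.blocks["tmb_by_outcome"] = {"skipped": str(exc)}

        # --- stage: survival --------------------------------------------
        try:
            comp = st.survival_compare(df["pfs_months"], df["pfs_event"],
                                       df["tmb_group"], group_order=["high", "low"])
            block = {"pfs_by_tmb_group": comp.result,
                     "observed": comp.observed, "expected": comp.expected}
            if self.reference is not None:
                quart = tq.stratify(df["percentile_rank"], "quartiles")
                block["percentile_quartile_logrank_p"] = self._logrank_trend(
                    df, quart.labels)
                block["percentile_quartile_cuts"] = list(quart.cut_points)
            results.blocks["survival"] = block
        except (TmbkitError, ValueError) as exc:
            results.blocks["survival"] = {"skipped": str(exc)}

        # --- stage: composite TMB x PD-L1 -------------------------------
        try:
            if df["pd_l1_pct"].notna().sum() == 0:
                results.blocks["composite"] = {"skipped": "PD-L1 missing for all patients"}
            else:
                labels = st.composite_groups(df["tmb_nonsyn"], df["pd_l1_pct"])
                usable = [l is not None for l in labels]
                trend = st.chi_square_trend(labels, df["responder"])
                results.blocks["composite"] = {
                    "labels": labels,
                    "n_missing_pd_l1": int(len(labels) - sum(usable)),
                    "trend_test": trend,
                    "spearman_pdl1_tmb": st.spearman(
                        df.loc[df["pd_l1_pct"].notna(), "tmb_nonsyn"],
                        df.loc[df["pd_l1_pct"].notna(), "pd_l1_pct"],
                    ),
                }
        except (TmbkitError, ValueError) as exc:
            results.blocks["composite"] = {"skipped": str(exc)}

        # --- stage: clonality + neoantigen burden -----------------------
        try:
            results.blocks["neoantigen"] = self._neoantigen_block(df)
        except (TmbkitError, ValueError) as exc:
            results.blocks["neoantigen"] = {"skipped": str(exc)}

        # --- stage: gene scan -------------------------------------------
        try:
            results.blocks["gene_scan"] = self._gene_scan(df, variants)
        except (TmbkitError, ValueError) as exc:
            results.blocks["gene_scan"] = {"skipped": str(exc)}

        # --- stage: multivariable adjustment ----------------------------
        try:
            mdf = df.rename(columns={"tmb_nonsyn": "tmb"})
            models = st.multivariable_models(
                mdf, covariates=("tmb", "pd_l1_pct", "squamous", "smoker", "ecog"),
            )
            results.blocks["multivariable"] = models
        except (TmbkitError, ValueError) as exc:
            results.blocks["multivariable"] = {"skipped": str(exc)}

        return results

    # -- block helpers ---------------------------------------------------

    def _tmb_by_outcome(self, df: pd.DataFrame) -> dict:
        r = df["responder"] == 1
        d = df["dcb"] == 1
        high = df["tmb_group"] == "high"
        orr_table = [[int((high & r).sum()), int((high & ~r).sum())],
                     [int((~high & r).sum()), int((~high & ~r).sum())]]
        dcb_table = [[int((high & d).sum()), int((high & ~d).sum())],
                     [int((~high & d).sum()), int((~high & ~d).sum())]]
        block = {
            "tmb_median_responder": float(df.loc[r, "tmb_nonsyn"].median()),
            "tmb_median_nonresponder": float(df.loc[~r, "tmb_nonsyn"].median()),
            "tmb_mw_response": st.mann_whitney(df.loc[r, "tmb_nonsyn"],
                                               df.loc[~r, "tmb_nonsyn"]),
            "tmb_mw_dcb": st.mann_whitney(df.loc[d, "tmb_nonsyn"],
                                          df.loc[~d, "tmb_nonsyn"]),
            "orr_by_tmb_group": st.fisher_2x2(orr_table),
            "dcb_by_tmb_group": st.fisher_2x2(dcb_table),
            "orr_high_pct": 100.0 * df.loc[high, "responder"].mean(),
            "orr_low_pct": 100.0 * df.loc[~high, "responder"].mean(),
            "dcb_high_pct": 100.0 * df.loc[high, "dcb"].mean(),
            "dcb_low_pct": 100.0 * df.loc[~high, "dcb"].mean(),
            "auc_response": st.roc_auc(df["tmb_nonsyn"], df["responder"]),
            "auc_dcb": st.roc_auc(df["tmb_nonsyn"], df["dcb"]),
            "auc_response_total_tmb": st.roc_auc(df["tmb_total"], df["responder"]),
        }
        for panel in self.panels:
            col = f"tmb_{panel.name}"
            if col in df:
                block[f"auc_response_{panel.name}"] = st.roc_auc(
                    df[col], df["responder"])
        return block

    def _logrank_trend(self, df: pd.DataFrame, labels) -> float:
        from lifelines.statistics import multivariate_logrank_test

        res = multivariate_logrank_test(df["pfs_months"], np.asarray(labels),
                                        df["pfs_event"])
        return float(res.p_value)

    def _neoantigen_block(self, df: pd.DataFrame) -> dict:
        if self.affinities is None:
            return {"skipped": "no affinity table provided"}
        clonality_map = None
        if self.ccf_inputs is not None:
            calls = cl.classify_variants(self.ccf_inputs)
            clonality_map = dict(zip(calls["mutation_key"], calls["clonality"]))
        profiles = neo.neoantigen_profiles(self.affinities, clonality_map)
        pframe = neo.profiles_to_frame(profiles).set_index("patient_id")
        joined = df.set_index("patient_id").join(pframe, how="inner")
        joined["n_candidates_500"] = joined["n_candidates_500"].fillna(0)
        block = {
            "profiles": pframe.reset_index(),
            "spearman_tmb_vs_candidates": st.spearman(
                joined["tmb_nonsyn"], joined["n_candidates_500"]),
        }
        if clonality_map is not None:
            n_clonal = sum(1 for v in clonality_map.values() if v == cl.CLONAL)
            block["n_clonal_mutations"] = n_clonal
            block["n_unresolved"] = sum(
                1 for v in clonality_map.values() if v == cl.UNRESOLVED)
        return block

    def _gene_scan(self, df: pd.DataFrame, variants, min_patients: int = 3) -> dict:
        vf = cio.variants_to_frame(variants)
        if vf.empty:
            return {"skipped": "no variants"}
        mat = (vf.groupby(["patient_id", "gene"]).size().unstack(fill_value=0) > 0)
        mat = mat.reindex(df["patient_id"]).fillna(False)
        recurrent = mat.columns[mat.sum(axis=0) >= min_patients]
        if len(recurrent) == 0:
            return {"skipped": f"no gene mutated in >= {min_patients} patients"}
        scan = st.gene_level_scan(mat[recurrent], df["responder"])
        return {"table": scan, "n_genes_tested": int((scan["skipped"] == "").sum())}


def contingency_report(orr_table, dcb_table=None) -> dict:
    """Table-mode analysis: association statistics straight from 2x2 counts.

    ``orr_table`` / ``dcb_table`` rows are (TMB-high, TMB-low), columns
    (outcome yes, outcome no). Returns the Fisher results plus per-group
    rates in percent, so printed contingency tables can be re-analyzed
    without patient-level data.
    """
    out = {}
    for name, table in (("orr", orr_table), ("dcb", dcb_table)):
        if table is None:
            continue
        t = np.asarray(table, dtype=float)
        res = st.fisher_2x2(t)
        out[name] = {
            "fisher": res,
            "rate_high_pct": 100.0 * t[0, 0] / t[0].sum(),
            "rate_low_pct": 100.0 * t[1, 0] / t[1].sum(),
        }
    return out
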
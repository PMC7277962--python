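"""End-to-end pipeline: simulate/load -> preprocess -> extract -> analyze.

The driver mirrors the study design: resting EEG is 0.1-100 Hz filtered
with a 60 Hz notch, segmented into 2.048-s epochs (reject > 100 μV, first
30 clean), and summarized as the low-alpha frontal asymmetry of F5/F6 and
F7/F8. ERP recordings are 0.1-30 Hz filtered, epoched around events
(-100..900 ms for the intensity series, -100..600 ms for the oddball,
reject ±75 μV after baseline correction) and summarized as the LDAEP slope
at Cz and the nine-site composite MMN. The cohort analysis median-splits
each biomarker and runs the outcome statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinstats, erp, io, sigproc, spectral
from .clinstats import HAMD_WEEKS
from .synthgen import SimulationConfig, draw_ground_truth, gen_clinical_cohort, \
    gen_ldaep_recording, gen_mmn_recording, gen_resting_eeg

__all__ = ["PipelineConfig", "extract_subject_features", "simulate_study",
           "analyze_cohort", "run_pipeline"]

log = logging.getLogger("erpmarkers")

ANALYSIS_INDICES = ("faa_f5f6", "faa_f7f8", "ldaep", "mmn", "mel")


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the study's reference values."""

    output_dir: str = None
    recordings_dir: str = None  # real-data mode: <subject>_<paradigm>.{edf,npz}
    clinical_table: str = None
    simulation: SimulationConfig = None  # synthetic mode when set
    # preprocessing
    resting_band: tuple = (0.1, 100.0)
    notch_hz: float = 60.0
    erp_band: tuple = (0.1, 30.0)
    resting_reject_uV: float = 100.0
    erp_reject_uV: float = 75.0
    resting_epoch_s: float = 2.048
    n_resting_epochs: int = 30
    # feature extraction
    alpha_band: tuple = spectral.LOW_ALPHA
    mmn_window: tuple = erp.MMN_WINDOW
    mmn_sites: tuple = erp.MMN_SITES
    ldaep_channel: str = "Cz"
    # statistics
    covariates: tuple = clinstats.COVARIATES
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.simulation = sim if isinstance(sim, SimulationConfig) \
                else SimulationConfig(**sim)
        return cfg

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def extract_subject_features(resting: sigproc.Recording,
                             ldaep_rec: sigproc.Recording,
                             mmn_rec: sigproc.Recording,
                             cfg: PipelineConfig = None) -> dict:
    """Run the full preprocessing + extraction chain for one subject."""
    cfg = cfg or PipelineConfig()
    feats = {"subject_id": resting.subject_id}

    r = sigproc.bandpass(resting, *cfg.resting_band)
    r = sigproc.notch(r, cfg.notch_hz)
    faa = spectral.compute_faa(r, band=cfg.alpha_band, epoch_s=cfg.resting_epoch_s,
                               reject_uV=cfg.resting_reject_uV,
                               max_epochs=cfg.n_resting_epochs)
    feats["faa_f5f6"] = faa["F5/F6"].value
    feats["faa_f7f8"] = faa["F7/F8"].value

    l = sigproc.bandpass(ldaep_rec, *cfg.erp_band)
    ep_l = sigproc.segment_events(l, post_ms=900.0, reject_uV=cfg.erp_reject_uV)
    feats["ldaep"] = erp.ldaep(ep_l, channel=cfg.ldaep_channel).slope
    feats["n_rejected_ldaep"] = ep_l.n_rejected

    m = sigproc.bandpass(mmn_rec, *cfg.erp_band)
    ep_m = sigproc.segment_events(m, post_ms=600.0, reject_uV=cfg.erp_reject_uV)
    res = erp.mmn(ep_m.select("standard"), ep_m.select("deviant"),
                  sites=cfg.mmn_sites, window=cfg.mmn_window)
    feats["mmn"] = res.composite
    feats["n_rejected_mmn"] = ep_m.n_rejected
    return feats


def simulate_study(sim: SimulationConfig, cfg: PipelineConfig = None,
                   extract: bool = True):
    """Simulate a full cohort and (optionally) run EEG feature extraction.

    Returns ``(features_df, clinical_records, truth)``. With
    ``extract=False`` the feature table carries the ground-truth biomarker
    values directly (useful for statistics-only simulations).
    """
    cfg = cfg or PipelineConfig()
    truth = draw_ground_truth(sim)
    records, truth = gen_clinical_cohort(sim, truth)
    rows = []
    for i, sid in enumerate(truth.subject_ids):
        if extract:
            resting = gen_resting_eeg(
                sim, sid, i, asym_targets={("F5", "F6"): truth.faa_f5f6[i],
                                           ("F7", "F8"): truth.faa_f7f8[i]})
            ldaep_rec = gen_ldaep_recording(sim, sid, i, slope=truth.ldaep_slope[i])
            mmn_rec = gen_mmn_recording(sim, sid, i, mmn_amp=truth.mmn_amp[i])
            row = extract_subject_features(resting, ldaep_rec, mmn_rec, cfg)
        else:
            row = {"subject_id": sid, "faa_f5f6": truth.faa_f5f6[i],
                   "faa_f7f8": truth.faa_f7f8[i], "ldaep": truth.ldaep_slope[i],
                   "mmn": truth.mmn_amp[i]}
        rows.append(row)
        log.info("extracted features for %s (%d/%d)", sid, i + 1, len(truth.subject_ids))
    return pd.DataFrame(rows), records, truth


def _long_hamd(clinical_df: pd.DataFrame, split: clinstats.SplitAssignment,
               covariates) -> pd.DataFrame:
    rows = []
    for _, r in clinical_df.iterrows():
        grp = split.groups.get(r["subject_id"])
        if grp is None:
            continue
        for w in HAMD_WEEKS:
            rows.append({"subject_id": r["subject_id"], "week": w,
                         "hamd": r[f"hamd_w{w}"], "group": grp,
                         **{c: r[c] for c in covariates}})
    return pd.DataFrame(rows)


def analyze_cohort(features: pd.DataFrame, clinical_df: pd.DataFrame,
                   cfg: PipelineConfig = None, indices=ANALYSIS_INDICES) -> dict:
    """Median split + outcome statistics for each biomarker index.

    ``features`` columns: subject_id, faa_f5f6, faa_f7f8, ldaep, mmn.
    ``clinical_df`` follows :data:`erpmarkers.io.CLINICAL_COLUMNS`; the
    melancholia index ("mel") is its ``core`` column.
    """
    cfg = cfg or PipelineConfig()
    df = features.merge(clinical_df, on="subject_id", validate="1:1")
    df["mel"] = df["core"]
    complete = df[[f"hamd_w{w}" for w in HAMD_WEEKS]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d subjects with incomplete HAM-D", n_dropped)
    df = df[complete].reset_index(drop=True)

    flags = {}
    for _, r in df.iterrows():
        rec = clinstats.ClinicalRecord(
            subject_id=r["subject_id"], age=r["age"], sex=r["sex"],
            medication=r["medication"],
            hamd={w: int(r[f"hamd_w{w}"]) for w in HAMD_WEEKS})
        flags[r["subject_id"]] = clinstats.classify_outcomes(rec)

    n = len(df)
    results = {
        "n_subjects": n,
        "n_dropped_incomplete": n_dropped,
        "remission_rate_pct": 100.0 * np.mean([f.remission for f in flags.values()]),
        "response_rate_pct": 100.0 * np.mean([f.response for f in flags.values()]),
        "indices": {},
    }
    covs = list(cfg.covariates)
    for index in indices:
        split = clinstats.median_split(
            df.set_index("subject_id")[index], index_name=index)
        entry = {"median": split.median,
                 "n_low": len(split.subjects("low")),
                 "n_high": len(split.subjects("high"))}
        for outcome in ("remission", "response"):
            table = clinstats.contingency(
                split, {s: getattr(f, outcome) for s, f in flags.items()})
            chi = clinstats.pearson_chi2(table)
            entry[outcome] = {
                "table": table.tolist(),
                "chi2": chi.statistic, "df": chi.df, "p": chi.p,
                "low_positive_pct": 100.0 * table[0, 0] / table[0].sum(),
                "high_positive_pct": 100.0 * table[1, 0] / table[1].sum(),
            }
        long = _long_hamd(df, split, covs)
        rm = clinstats.rm_ancova(long, covariates=covs,
                                 sphericity_alpha=cfg.alpha)
        entry["rm_ancova"] = dataclasses.asdict(rm)
        entry["ancova_by_week"] = {
            int(w): dataclasses.asdict(clinstats.ancova_at_week(long, w, covariates=covs))
            for w in HAMD_WEEKS}
        results["indices"][index] = entry

    # partial correlations of melancholia score with the EEG biomarkers
    cov_df = df[covs]
    results["partial_corr_mel"] = {
        index: dataclasses.asdict(clinstats.partial_corr(df[index], df["mel"], cov_df))
        for index in ("faa_f5f6", "faa_f7f8", "ldaep", "mmn")}
    return results


def _fmt_p(p: float) -> str:
    return f"{p:.3f}" if p >= 0.001 else "<0.001"


def render_report(results: dict, alpha: float = 0.05) -> str:
    """Human-readable summary of the results bundle."""
    lines = [
        "ERP biomarker outcome analysis",
        "=" * 34,
        f"n = {results['n_subjects']} subjects "
        f"({results['n_dropped_incomplete']} dropped incomplete)",
        f"remission rate: {results['remission_rate_pct']:.2f}%   "
        f"response rate: {results['response_rate_pct']:.2f}%",
        "",
        "Note: no multiple-testing correction is applied across the indices.",
        "",
    ]
    for index, e in results["indices"].items():
        lines.append(f"[{index}]  median {e['median']:.3f}  "
                     f"(low n={e['n_low']}, high n={e['n_high']})")
        for outcome in ("remission", "response"):
            o = e[outcome]
            star = " *" if o["p"] < alpha else ""
            lines.append(
                f"  {outcome:9s} low {o['low_positive_pct']:.2f}% vs "
                f"high {o['high_positive_pct']:.2f}%  "
                f"X2(1) = {o['chi2']:.2f}, p = {_fmt_p(o['p'])}{star}")
        rm = e["rm_ancova"]
        star = " *" if rm["p"] < alpha else ""
        lines.append(
            f"  week x group  F({rm['df1']:.3f}, {rm['df2']:.3f}) = {rm['F']:.2f}, "
            f"p = {_fmt_p(rm['p'])}{star}  (GG eps = {rm['epsilon']:.4f}, "
            f"Mauchly p = {_fmt_p(rm['mauchly_p'])})")
        for w, a in e["ancova_by_week"].items():
            gm = a["group_means"]
            star = " *" if a["p"] < alpha else ""
            lines.append(
                f"    week {w}: low {gm['low'][0]:.2f} ± {gm['low'][1]:.2f}, "
                f"high {gm['high'][0]:.2f} ± {gm['high'][1]:.2f}; "
                f"F({a['df1']},{a['df2']}) = {a['F']:.2f}, p = {_fmt_p(a['p'])}{star}")
        lines.append("")
    lines.append("partial correlation with melancholia score "
                 "(controlling age, sex, baseline HAM-D, medication):")
    for index, pc in results["partial_corr_mel"].items():
        star = " *" if pc["p"] < alpha else ""
        lines.append(f"  {index:9s} r = {pc['r']:+.2f}, df = {pc['df']}, "
                     f"p = {_fmt_p(pc['p'])}{star}")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured pipeline and write the results bundle.

    Synthetic mode (``cfg.simulation`` set) simulates the cohort; real-data
    mode reads recordings from ``cfg.recordings_dir`` (files named
    ``<subject>_<paradigm>.edf`` or ``.npz``) and the clinical table from
    ``cfg.clinical_table``. Deterministic given the configuration and seed.
    """
    if cfg.simulation is not None:
        features, records, truth = simulate_study(cfg.simulation, cfg)
        clinical_df = io.clinical_to_frame(records)
    else:
        if not cfg.recordings_dir or not cfg.clinical_table:
            raise ValueError("need either a simulation block or recordings_dir "
                             "+ clinical_table")
        records = io.read_clinical_table(cfg.clinical_table)
        clinical_df = io.clinical_to_frame(records)
        truth = None
        rows = []
        root = Path(cfg.recordings_dir)
        for rec in records:
            recs = {}
            for paradigm in ("resting", "ldaep", "mmn"):
                hits = sorted(root.glob(f"{rec.subject_id}_{paradigm}.*"))
                hits = [h for h in hits if h.suffix.lower() in {".edf", ".npz"}]
                if not hits:
                    raise FileNotFoundError(
                        f"no {paradigm} recording for subject {rec.subject_id} "
                        f"in {root}")
                recs[paradigm] = io.read_recording(hits[0], paradigm=paradigm)
            rows.append(extract_subject_features(
                recs["resting"], recs["ldaep"], recs["mmn"], cfg))
        features = pd.DataFrame(rows)

    results = analyze_cohort(features, clinical_df, cfg)
    results["provenance"] = cfg.provenance()

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        clinical_df.to_csv(out / "clinical.csv", index=False)
        if truth is not None:
            io.write_ground_truth(truth, out / "ground_truth.json")
        (out / "results.json").write_text(json.dumps(results, indent=1, default=str))
        (out / "report.txt").write_text(render_report(results, cfg.alpha))
        log.info("results bundle written to %s", out)
    return results
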
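"""End-to-end orchestration: simulate/load → epoch → spectra + connectivity
→ group statistics → PLSC, with deterministic re-runs.

The pipeline operates on source-level recordings (beamforming is applied
only when sensor-level data plus a lead field are supplied) and persists
every intermediate product.  A single global seed is fanned out to
per-stage independent generators through ``numpy.random.SeedSequence``
spawning (stage tag, then subject index), so identical config + inputs +
seed yield an identical results bundle, and individual stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import DEFAULT_BANDS
from .connectivity import connectivity_matrix, summarize_connectivity
from .epoching import (DEFAULT_EPOCH_LEN, SubjectExclusionError, segment,
                       score_epochs, select_epochs)
from .groupstats import (RSN_ORDER, ancova_group_test, bh_fdr,
                         rsn_effect_contribution, rsn_majority_vote,
                         spearman_grid)
from .io import (read_cohort, read_parcellation, read_recording,
                 list_subjects, write_cohort, FLOAT_FMT)
from .plsc import PLSCInput, impute_knn, plsc_bootstrap, plsc_permutation
from .synthdata import (CouplingSpec, SimSpec, gen_cohort_table,
                        gen_source_timeseries)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "write_bundle"]

log = logging.getLogger("megrest")

COGNITIVE_VARS = ("MMSE", "fluency", "TMTB", "CERAD", "cCAQ", "pCAQ")


@dataclass
class PipelineConfig:
    """Run configuration; serialisable to/from JSON.

    With ``input_container`` unset, a synthetic cohort is generated from
    the ``sim`` block (a :class:`~megrest.synthdata.SimSpec` field dict).
    """

    output_dir: str = "results"
    input_container: str | None = None
    cohort_csv: str | None = None
    parcellation_tsv: str | None = None
    bands: tuple[str, ...] = tuple(DEFAULT_BANDS.names)
    connectivity_bands: tuple[str, ...] = tuple(DEFAULT_BANDS.names)
    epoch_len: int = DEFAULT_EPOCH_LEN
    n_epochs: int = 8
    covariates: tuple[str, ...] = ("age", "gender")
    fdr_q: float = 0.05
    n_perm: int = 1000
    n_boot: int = 500
    z_thresh: float = 3.0
    k_impute: int = 4
    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("bands", "connectivity_bands", "covariates"):
            d[key] = list(d[key])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def sim_spec(self) -> SimSpec:
        kwargs = dict(self.sim)
        pairs = kwargs.pop("coupling_pairs", None)
        if pairs is not None:
            kwargs["coupling_pairs"] = tuple(
                CouplingSpec(**p) if isinstance(p, dict) else CouplingSpec(*p)
                for p in pairs
            )
        kwargs.setdefault("epoch_len", self.epoch_len)
        kwargs.setdefault("seed", self.seed)
        return SimSpec(**kwargs)

    def validate(self) -> None:
        for name in ("input_container", "cohort_csv", "parcellation_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")


@dataclass
class ResultsBundle:
    spectral: pd.DataFrame            # tidy: subject, roi, band, rbp, total_power
    ipf: pd.Series                    # per subject, Hz
    connectivity: pd.DataFrame        # tidy: subject, band, whole_brain, roi, strength
    conn_matrices: dict               # (subject, band) -> ConnectivityMatrix
    cohort: object                    # CohortTable
    group_tests: pd.DataFrame         # feature, F, p, d, p_adj, significant
    regional_tests: pd.DataFrame      # band, roi, F, p, d, p_adj, significant
    rsn_contributions: pd.DataFrame   # band × network percentages
    spearman: object                  # SpearmanGrid
    plsc: dict                        # block name -> PLSCResult
    manifest: dict


def _gender_code(series: pd.Series) -> np.ndarray:
    # binary indicator, reference level F (coded 0)
    return (series.astype(str).str.upper() == "M").to_numpy(dtype=float)


def _stage(msg: str) -> None:
    log.info(msg)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute all stages; see module docstring for determinism contract."""
    config.validate()
    scheme = DEFAULT_BANDS
    band_names = [b for b in config.bands]

    # --- data acquisition --------------------------------------------------
    truth = None
    if config.input_container:
        _stage("loading recordings")
        subjects = list_subjects(config.input_container)
        recordings = [read_recording(config.input_container, s) for s in subjects]
    else:
        _stage("simulating cohort")
        spec = config.sim_spec()
        recordings, truth = gen_source_timeseries(spec)
        subjects = [r.subject_id for r in recordings]
    occipital_idx = (list(config.sim_spec().occipital_idx)
                     if not config.input_container else
                     list(range(min(8, recordings[0].n_regions))))
    roi_names = recordings[0].roi_names

    # --- epoch selection ---------------------------------------------------
    _stage("epoch selection")
    esets = {}
    excluded = []
    for rec in recordings:
        try:
            scored = score_epochs(segment(rec, config.epoch_len), occipital_idx)
            esets[rec.subject_id] = select_epochs(scored, config.n_epochs)
        except SubjectExclusionError as err:
            log.warning(str(err))
            excluded.append(rec.subject_id)
    subjects = [s for s in subjects if s not in excluded]

    # --- spectral ----------------------------------------------------------
    _stage("spectral analysis")
    from .spectral import subject_spectral_profile
    profiles = {s: subject_spectral_profile(esets[s], scheme, occipital_idx)
                for s in subjects}
    rows = []
    for s, prof in profiles.items():
        for r, roi in enumerate(roi_names):
            for b, band in enumerate(scheme.names):
                rows.append((s, roi, band, prof.rbp[r, b], prof.total_power[r]))
    spectral_df = pd.DataFrame(
        rows, columns=["subject", "roi", "band", "rbp", "total_power"])
    ipf = pd.Series({s: profiles[s].ipf for s in subjects}, name="ipf")

    # whole-brain features for the cohort table / PLSC brain block
    feat = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
    for band in scheme.names:
        feat[f"{band}_rbp"] = [profiles[s].rbp[:, scheme.names.index(band)].mean()
                               for s in subjects]
    feat["ipf"] = [profiles[s].ipf for s in subjects]

    # --- cohort ------------------------------------------------------------
    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)
    else:
        _stage("generating cohort table")
        spec = config.sim_spec()
        bf = feat.copy()
        bf["group"] = [spec.group_of(s) for s in subjects]
        cohort = gen_cohort_table(spec, bf)
    cohort_df = cohort.data.loc[subjects]
    group = cohort_df["group"].to_numpy()

    # --- connectivity ------------------------------------------------------
    _stage("connectivity (AECc)")
    conn_matrices = {}
    conn_rows = []
    for band in config.connectivity_bands:
        for s in subjects:
            cm = connectivity_matrix(esets[s], band, scheme)
            conn_matrices[(s, band)] = cm
            summ = summarize_connectivity(cm)
            for r, roi in enumerate(roi_names):
                conn_rows.append((s, band, summ.whole_brain, roi,
                                  summ.nodal_strength[r]))
    conn_df = pd.DataFrame(
        conn_rows, columns=["subject", "band", "whole_brain", "roi", "strength"])

    # --- parcellation ------------------------------------------------------
    if config.parcellation_tsv:
        rsn_map = read_parcellation(config.parcellation_tsv).reindex(roi_names)
    else:
        # synthetic label-count table voted into a map, keyed on the seed
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(len(roi_names), len(RSN_ORDER))),
            index=pd.Index(roi_names, name="roi"), columns=list(RSN_ORDER))
        rsn_map = rsn_majority_vote(counts)

    # --- group statistics --------------------------------------------------
    _stage("group statistics")
    gind = (group == group[0]).astype(float)
    base = np.column_stack([np.ones(len(group)), gind])
    kept = []
    for c in config.covariates:
        col = (_gender_code(cohort_df[c]) if c == "gender"
               else cohort_df[c].to_numpy(dtype=float))
        cand = np.column_stack([base] + [k[1] for k in kept] + [col])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept.append((c, col))
        else:
            log.warning("covariate %r collinear with the design; dropped", c)
    cov = np.column_stack([k[1] for k in kept]) if kept else None

    gt_rows = []
    for band in scheme.names:
        res = ancova_group_test(feat[f"{band}_rbp"].to_numpy(), group, cov,
                                feature_id=f"{band}_rbp")
        gt_rows.append(res)
    gt_rows.append(ancova_group_test(feat["ipf"].to_numpy(), group, cov,
                                     feature_id="ipf"))
    for band in config.connectivity_bands:
        wb = (conn_df[conn_df.band == band]
              .groupby("subject")["whole_brain"].first().loc[subjects])
        gt_rows.append(ancova_group_test(wb.to_numpy(), group, cov,
                                         feature_id=f"{band}_aecc"))
    rej, p_adj = bh_fdr(np.array([r.p for r in gt_rows]), config.fdr_q)
    group_tests = pd.DataFrame({
        "feature": [r.feature_id for r in gt_rows],
        "F": [r.F for r in gt_rows], "p": [r.p for r in gt_rows],
        "d": [r.cohens_d for r in gt_rows],
        "p_adj": p_adj, "significant": rej,
        "sign_convention": [r.sign_convention for r in gt_rows],
    })

    # region-wise RBP tests per band + RSN contributions
    reg_rows = []
    rsn_rows = {}
    pivot = spectral_df.pivot_table(index="subject", columns=["band", "roi"],
                                    values="rbp").loc[subjects]
    for band in band_names:
        stats_b = [ancova_group_test(pivot[(band, roi)].to_numpy(), group, cov,
                                     feature_id=roi) for roi in roi_names]
        rejb, padjb = bh_fdr(np.array([r.p for r in stats_b]), config.fdr_q)
        for r, roi in enumerate(roi_names):
            reg_rows.append((band, roi, stats_b[r].F, stats_b[r].p,
                             stats_b[r].cohens_d, padjb[r], rejb[r]))
        d_vec = np.array([r.cohens_d for r in stats_b])
        if rejb.any():
            rsn_rows[band] = rsn_effect_contribution(d_vec, rejb, rsn_map)
        else:
            rsn_rows[band] = pd.Series(
                0.0, index=[n for n in RSN_ORDER if n in set(rsn_map)])
    regional_tests = pd.DataFrame(
        reg_rows, columns=["band", "roi", "F", "p", "d", "p_adj", "significant"])
    rsn_contributions = pd.DataFrame(rsn_rows).T.rename_axis("band")

    # --- Spearman grid across cognitive variables --------------------------
    spear_cols = [c for c in ("age", "education", *COGNITIVE_VARS)
                  if c in cohort_df.columns]
    spear = spearman_grid(cohort_df[spear_cols], config.fdr_q)

    # --- PLSC --------------------------------------------------------------
    _stage("PLSC")
    y_cols = [c for c in (*COGNITIVE_VARS, "education", "age")
              if c in cohort_df.columns]
    Y = impute_knn(cohort_df[y_cols], config.k_impute).to_numpy()
    plsc_out = {}
    blocks = {"spectral": feat[[f"{b}_rbp" for b in scheme.names] + ["ipf"]]}
    wb_cols = {}
    for band in config.connectivity_bands:
        wb_cols[f"{band}_aecc"] = (conn_df[conn_df.band == band]
                                   .groupby("subject")["whole_brain"]
                                   .first().loc[subjects].to_numpy())
    if wb_cols:
        blocks["connectivity"] = pd.DataFrame(wb_cols, index=feat.index)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    for name, X in blocks.items():
        inp = PLSCInput(X.to_numpy(), Y, list(X.columns), y_cols)
        res = plsc_bootstrap(inp, config.n_boot, config.z_thresh, rng)
        res.perm_p, res.perm_p_fdr = plsc_permutation(
            inp, config.n_perm, config.fdr_q, rng)
        plsc_out[name] = res

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "n_subjects": len(subjects),
        "excluded_subjects": excluded,
    }
    return ResultsBundle(
        spectral=spectral_df, ipf=ipf, connectivity=conn_df,
        conn_matrices=conn_matrices, cohort=cohort, group_tests=group_tests,
        regional_tests=regional_tests, rsn_contributions=rsn_contributions,
        spearman=spear, plsc=plsc_out, manifest=manifest,
    )


def write_bundle(bundle: ResultsBundle, out_dir) -> None:
    """Persist a results bundle as CSV/TSV/JSON files plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = bundle.manifest["config_hash"]
    kw = dict(index=False, float_format=FLOAT_FMT)
    bundle.spectral.to_csv(out / f"spectral_{h}.csv", **kw)
    bundle.ipf.rename_axis("subject").reset_index().to_csv(
        out / f"ipf_{h}.csv", **kw)
    bundle.connectivity.to_csv(out / f"connectivity_{h}.csv", **kw)
    bundle.group_tests.to_csv(out / f"group_tests_{h}.csv", **kw)
    bundle.regional_tests.to_csv(out / f"regional_tests_{h}.csv", **kw)
    bundle.rsn_contributions.reset_index().to_csv(
        out / f"rsn_contributions_{h}.csv", **kw)
    write_cohort(bundle.cohort, out / f"cohort_{h}.csv")
    for (s, band), cm in bundle.conn_matrices.items():
        df = pd.DataFrame(cm.matrix)
        df.to_csv(out / f"aecc_{s}_{band}_{h}.csv",
                  index=False, float_format=FLOAT_FMT)
    plsc_json = {}
    for name, res in bundle.plsc.items():
        plsc_json[name] = {
            "singular_values": res.singular_values.tolist(),
            "r_squared": res.r_squared.tolist(),
            "perm_p": res.perm_p.tolist(),
            "perm_p_fdr": res.perm_p_fdr.tolist(),
        }
        loadings = pd.DataFrame({
            "block": ["brain"] * res.brain_loadings.shape[0]
                     + ["cognitive"] * res.cognitive_loadings.shape[0],
            "variable": list(range(res.brain_loadings.shape[0]))
                        + list(range(res.cognitive_loadings.shape[0])),
        })
        for c in range(res.n_components):
            loadings[f"loading_{c}"] = np.concatenate(
                [res.brain_loadings[:, c], res.cognitive_loadings[:, c]])
            loadings[f"z_{c}"] = np.concatenate(
                [res.boot_z_brain[:, c], res.boot_z_cognitive[:, c]])
            loadings[f"reliable_{c}"] = np.concatenate(
                [res.reliable_brain[:, c], res.reliable_cognitive[:, c]])
        loadings.to_csv(out / f"plsc_{name}_loadings_{h}.csv", **kw)
    with open(out / f"plsc_{h}.json", "w", encoding="utf-8") as fh:
        json.dump(plsc_json, fh, indent=2)
    with open(out / f"manifest_{h}.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2)
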
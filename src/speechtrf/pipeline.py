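"""End-to-end orchestration: simulate -> features -> residualize -> fit ->
response analysis -> group statistics.

``run_pipeline`` executes the full analysis on a synthetic cohort and
returns (and optionally writes) a report bundle: the per-participant
encoding-accuracy table, RMS tables, peak/window/inclusion tables, the
mixed-model coefficient tables for all three formulas, EMM post-hocs of the
PTA x word-segmentation interaction, and Mann-Whitney group comparisons of
peak amplitudes and latencies. The bundle is a pure function of the
configuration, including its master seed.

The stimulus-side sufficient statistics (lagged nuisance Grams, per-fold
feature Grams) are computed once and shared across participants, since the
speech features are identical for everyone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .boosting import CVSchedule, FoldStats, TRFFit, fit_mtrf, make_cv_schedule
from .design import LAG_SAMPLES, LaggedNuisance
from .features import MODEL_SPECS
from .response import available_clusters, peak_table, rms_table
from .stats import StatsError, emm_at_pta, fit_lmm, holm_adjust, mann_whitney, spearman_fisher
from .synthetic import SyntheticConfig, SyntheticDataset, make_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineOptions:
    """Analysis-stage knobs (the study-design knobs live in SyntheticConfig)."""

    step: float = 0.005
    patience: int = 32
    max_iter: int = 10_000
    nuisance_lags: str = "trf"  # "trf" (full lag axis) | "none" (lag 0 only)
    n_boot: int = 0  # parametric-bootstrap CI resamples in the LMM reports
    moca: str = "binary"  # or "continuous" (supplementary variant)
    models: tuple[str, ...] = tuple(MODEL_SPECS)


@dataclass
class PipelineReport:
    config: SyntheticConfig
    options: PipelineOptions
    accuracy: pd.DataFrame  # participant x model encoding accuracy + covariates
    rms: pd.DataFrame
    peaks: pd.DataFrame
    inclusion: pd.DataFrame
    boundaries: dict
    lmm_accuracy: pd.DataFrame
    emm: pd.DataFrame
    lmm_rms: dict  # model -> coefficient table
    group_tests: pd.DataFrame
    summary: dict
    fits: Mapping[str, Mapping[str, TRFFit]]
    dataset: SyntheticDataset


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def fit_all_models(
    dataset: SyntheticDataset,
    options: PipelineOptions = PipelineOptions(),
    schedule: CVSchedule | None = None,
) -> dict[str, dict[str, TRFFit]]:
    """Residualize and fit every model for every participant.

    Returns participant_id -> model_name -> TRFFit.
    """
    cfg = dataset.config
    schedule = schedule or make_cv_schedule(range(cfg.n_segments))
    electrodes = dataset.electrodes
    sr = cfg.sample_rate
    skip = sr  # first second dropped in the TRF stage
    nuis_lags = LAG_SAMPLES if options.nuisance_lags == "trf" else np.array([0])

    fits: dict[str, dict[str, TRFFit]] = {
        p.participant_id: {} for p in dataset.participants
    }
    for mname in options.models:
        spec = MODEL_SPECS[mname]
        nuisance = LaggedNuisance(
            [fs.as_array(spec.nuisance_features) for fs in dataset.feature_sets],
            nuis_lags,
        )
        blocks = [fs.as_array(spec.features_of_interest)[:, skip:]
                  for fs in dataset.feature_sets]
        shared = FoldStats(blocks, schedule)
        for i, p in enumerate(dataset.participants):
            resid = nuisance.residualize(dataset.eeg[i])
            fits[p.participant_id][mname] = fit_mtrf(
                spec, dataset.feature_sets, resid, schedule,
                electrodes=electrodes, step=options.step,
                patience=options.patience, max_iter=options.max_iter,
                _fold_stats=shared,
            )
    return fits


def accuracy_table(
    dataset: SyntheticDataset, fits: Mapping[str, Mapping[str, TRFFit]]
) -> pd.DataFrame:
    """Long table: participant, model, electrode-mean encoding accuracy,
    with MoCA group/score and standardized PTA covariates."""
    pta_z = dataset.pta_z
    rows = []
    for i, p in enumerate(dataset.participants):
        for mname, fit in fits[p.participant_id].items():
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "model": mname,
                    "accuracy": fit.accuracy_mean,
                    "moca_group": p.moca_group,
                    "moca_score": p.moca_score,
                    "pta": p.pta,
                    "pta_z": pta_z[i],
                    "age": p.age,
                }
            )
    return pd.DataFrame(rows)


def group_peak_tests(peaks: pd.DataFrame, inclusion: pd.DataFrame,
                     meta: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney normal-vs-low comparisons of peak amplitude and latency.

    Only cells passing the 75% occurrence rule enter; Holm correction is
    applied within one (feature, window, measure) family across clusters.
    """
    meta_g = meta.set_index("participant_id")["moca_group"]
    rows = []
    included = inclusion[inclusion.included]
    for (feature, window), cells in included.groupby(["feature", "window"]):
        for measure, col in (("amplitude", "amplitude"), ("latency", "latency_ms")):
            fam = []
            for cluster in cells.cluster:
                sel = peaks[
                    (peaks.feature == feature)
                    & (peaks.window == window)
                    & (peaks.cluster == cluster)
                ]
                g = meta_g.loc[sel.participant_id].to_numpy()
                x = sel.loc[g == "normal", col].to_numpy()
                y = sel.loc[g == "low", col].to_numpy()
                if len(x) < 2 or len(y) < 2:
                    continue
                r = mann_whitney(x, y)
                fam.append((cluster, len(x), len(y), r))
            if not fam:
                continue
            p_adj = holm_adjust([r.p_raw for _, _, _, r in fam])
            for (cluster, n1, n2, r), pc in zip(fam, p_adj):
                rows.append(
                    {
                        "feature": feature,
                        "window": window,
                        "measure": measure,
                        "cluster": cluster,
                        "U": r.U,
                        "p_raw": r.p_raw,
                        "p_corr": float(pc),
                        "r": r.r,
                        "n_normal": n1,
                        "n_low": n2,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["feature", "window", "measure", "cluster", "U", "p_raw",
                 "p_corr", "r", "n_normal", "n_low"],
    )


def run_pipeline(
    config: SyntheticConfig | None = None,
    options: PipelineOptions = PipelineOptions(),
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the complete synthetic-cohort analysis; see the module docstring."""
    config = config or SyntheticConfig()

    dataset = _stage("simulate")(make_dataset)(config)
    fits = _stage("fit")(fit_all_models)(dataset, options)
    acc = accuracy_table(dataset, fits)

    clusters = available_clusters(dataset.electrodes)
    rms = _stage("analyze")(rms_table)(fits, clusters)
    peaks, inclusion = _stage("analyze")(peak_table)(fits, clusters=clusters)
    boundaries = dict(
        inclusion.groupby("feature")["boundary_ms"].first()
    )

    meta = acc.drop_duplicates("participant_id")[
        ["participant_id", "moca_group", "moca_score", "pta", "pta_z", "age"]
    ]

    # Statistics
    lmm_acc = _stage("stats")(fit_lmm)(
        acc, "encoding_accuracy", moca=options.moca, n_boot=options.n_boot,
        seed=config.master_seed,
    )
    emm = emm_at_pta(lmm_acc, "seg_word")
    lmm_rms = {}
    for mname in options.models:
        sub = rms[(rms.model == mname) & (rms.cluster != "")].merge(
            meta, on="participant_id"
        )
        formula = (
            "rms_two_feature" if sub.feature.nunique() == 2 else "rms_one_feature"
        )
        try:
            lmm_rms[mname] = fit_lmm(
                sub, formula, moca=options.moca, n_boot=options.n_boot,
                seed=config.master_seed,
            ).coefficients
        except (StatsError, np.linalg.LinAlgError) as e:
            logger.warning("RMS LMM for %s failed: %s", mname, e)
    gtests = group_peak_tests(peaks, inclusion, meta)

    rho, rho_p, fz = spearman_fisher(meta.pta, meta.age)
    mw_age = mann_whitney(meta.loc[meta.moca_group == "normal", "age"],
                          meta.loc[meta.moca_group == "low", "age"])
    mw_pta = mann_whitney(meta.loc[meta.moca_group == "normal", "pta"],
                          meta.loc[meta.moca_group == "low", "pta"])

    emm_est = emm.estimate.to_numpy()
    interaction_slope = float((emm_est[-1] - emm_est[0]) /
                              (emm.pta_z.iloc[-1] - emm.pta_z.iloc[0]))
    coef = lmm_acc.coefficients.set_index("term")
    summary = {
        "config": asdict(config),
        "n_participants": config.n_participants,
        "accuracy_by_model": {
            m: float(acc.loc[acc.model == m, "accuracy"].mean())
            for m in options.models
        },
        "emm_acoustic_minus_seg_word": {
            f"pta_z={z:+.0f}": float(e) for z, e in zip(emm.pta_z, emm_est)
        },
        "pta_x_seg_word_interaction_slope": interaction_slope,
        "pta_x_seg_word_sum_coefficient": float(coef.loc["pta_z:model_seg_word", "beta"])
        if "pta_z:model_seg_word" in coef.index else None,
        "pta_age_spearman": {"rho": rho, "p": rho_p, "fisher_z": fz},
        "group_age_mw": {"U": mw_age.U, "p": mw_age.p_raw, "r": mw_age.r},
        "group_pta_mw": {"U": mw_pta.U, "p": mw_pta.p_raw, "r": mw_pta.r},
        "window_boundaries_ms": {k: float(v) for k, v in boundaries.items()},
    }

    report = PipelineReport(
        config=config, options=options, accuracy=acc, rms=rms, peaks=peaks,
        inclusion=inclusion, boundaries=boundaries,
        lmm_accuracy=lmm_acc.coefficients, emm=emm, lmm_rms=lmm_rms,
        group_tests=gtests, summary=summary, fits=fits, dataset=dataset,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


# ---------------------------------------------------------------------------
# Real-data entry points
# ---------------------------------------------------------------------------


def real_feature_set(
    wav_path,
    textgrid_path,
    pronunciation_path,
    frequency_path,
    *,
    word_tier: str = "words",
    phone_tier: str = "phones",
    surprisal=None,
) -> "SpeechFeatureSet":
    """Build one segment's feature set from recorded-study input files.

    Reads a mono WAV, a forced-alignment TextGrid, an MFA-style
    pronunciation dictionary and a unigram frequency table; computes the
    gammatone envelope and assembles all eight regressor channels. The EEG
    itself is supplied separately (see :func:`load_eeg_npz`).
    """
    from .features import assemble_features, extract_envelope, load_wav
    from .lexicon import build_lexicon, read_frequency_table, read_pronunciation_dict
    from .transcript import read_textgrid

    for p in (wav_path, textgrid_path, pronunciation_path, frequency_path):
        if not Path(p).exists():
            raise PipelineError(f"missing input file: {p}")
    transcript = read_textgrid(textgrid_path, word_tier, phone_tier)
    prons = read_pronunciation_dict(pronunciation_path)
    freqs = read_frequency_table(frequency_path)
    lexicon = build_lexicon(prons, freqs,
                            {w.orthography for w in transcript.words})
    wave, rate = load_wav(wav_path)
    env = extract_envelope(wave, rate, duration=transcript.duration)
    return assemble_features(transcript, env, lexicon, surprisal=surprisal)


def load_eeg_npz(path) -> np.ndarray:
    """Load preprocessed EEG (segments x electrodes x samples at 128 Hz)
    from an .npz archive with an ``eeg`` array."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"missing input file: {path}")
    with np.load(path) as data:
        if "eeg" not in data:
            raise PipelineError(f"{path} has no 'eeg' array")
        eeg = np.asarray(data["eeg"], dtype=float)
    if eeg.ndim != 3:
        raise PipelineError("EEG array must be segments x electrodes x samples")
    return eeg


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.accuracy.to_csv(out_dir / "encoding_accuracy.csv", index=False)
    report.rms.to_csv(out_dir / "rms.csv", index=False)
    report.peaks.to_csv(out_dir / "peaks.csv", index=False)
    report.inclusion.to_csv(out_dir / "peak_inclusion.csv", index=False)
    report.lmm_accuracy.to_csv(out_dir / "lmm_accuracy_table1.csv", index=False)
    report.emm.to_csv(out_dir / "emm_posthoc.csv", index=False)
    for m, tab in report.lmm_rms.items():
        tab.to_csv(out_dir / f"lmm_rms_{m}_table2.csv", index=False)
    report.group_tests.to_csv(out_dir / "peak_group_tests_table3.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True)
    )
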
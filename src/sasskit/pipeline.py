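"""End-to-end orchestration: simulate, analyze, cross-validate, heartbeat.

Every run writes tab-separated tables next to any figure so that each plot
has a machine-readable sidecar, plus a JSON manifest (inputs, configuration,
seed, package versions) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .events import EventSeries, detect_flicker_events, segment_trials
from .exceptions import DegenerateDataError
from .heartbeat import detect_r_peaks, permutation_pvalues
from .io import OCCIPITAL_SET, Recording, read_brainvision, standard_montage_64, write_brainvision
from .sass import sass_fit, sass_multiband
from .spectral import BandSpec, amplitude_topography, trial_phase_amplitude, virtual_channel, welch_psd
from .stats import amplitude_tests, group_tests, plv, wallraff_test
from .synth import SynthConfig, generate_session

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_crossval", "run_heartbeat"]

CONDITIONS = ("no_stim", "stim_sass", "stim_raw")


@dataclass
class RunConfig:
    """Configuration of an analysis run."""

    no_stim_path: str | None = None
    stim_path: str | None = None
    out_dir: str = "sasskit_out"
    band: BandSpec = field(default_factory=BandSpec)
    occipital_set: tuple = OCCIPITAL_SET
    centers: tuple = ()  # extra harmonics for multiband SASS
    f_flicker: float = 10.0
    trial_window: tuple = (0.0, 2.0)
    crossval: bool = False
    seed: int = 0
    figures: bool = True

    def __post_init__(self):
        for p in (self.no_stim_path, self.stim_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(out_dir: str, seed: int, config: dict, inputs=()):
    import mne
    import scipy

    man = {
        "sasskit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "mne": mne.__version__,
        "seed": seed,
        "config": config,
        "inputs": {p: _sha256(p) for p in inputs if p and os.path.exists(p)},
    }
    man["config_hash"] = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(man, fh, indent=1, sort_keys=True, default=str)
    return man


def run_simulate(cfg: SynthConfig, out_dir: str, heartbeat: bool = False):
    """Generate a no-stim/stim session pair, write BrainVision triples and
    columnar ground-truth sidecars; returns the four base paths."""
    os.makedirs(out_dir, exist_ok=True)
    if heartbeat:
        cfg.heartbeat.enabled = True
    paths = {}
    for name, with_stim in (("no_stim", False), ("stim", True)):
        rec, truth = generate_session(cfg, with_stim=with_stim)
        base = os.path.join(out_dir, name)
        write_brainvision(rec, base)
        tbl = pd.DataFrame(
            {
                "trial": np.arange(len(truth.trial_onsets)),
                "onset_sample": truth.trial_onsets,
                "true_amplitude_uV": truth.true_trial_amplitude,
                "true_phase_rad": truth.true_trial_phase,
            }
        )
        tbl.to_csv(base + "_truth.tsv", sep="\t", index=False)
        if truth.r_peak_samples is not None:
            np.savetxt(base + "_rpeaks.txt", truth.r_peak_samples, fmt="%d")
        paths[name] = base
    _manifest(out_dir, cfg.seed, cfg.to_dict())
    return paths


def _load_pair(cfg: RunConfig):
    no_stim = read_brainvision(cfg.no_stim_path)
    stim = read_brainvision(cfg.stim_path)
    return no_stim, stim


def _trial_events(rec: Recording) -> EventSeries:
    return segment_trials(detect_flicker_events(rec.audio(), rec.fs))


def _condition_metrics(cfg: RunConfig, no_stim, stim, model, ev0, ev1):
    tmin, tmax = cfg.trial_window
    kw = dict(
        band=cfg.band,
        occipital_set=cfg.occipital_set,
        f_flicker=cfg.f_flicker,
        tmin=tmin,
        tmax=tmax,
    )
    return {
        "no_stim": trial_phase_amplitude(no_stim, ev0, **kw),
        "stim_sass": trial_phase_amplitude(stim, ev1, projection=model.P, **kw),
        "stim_raw": trial_phase_amplitude(stim, ev1, **kw),
    }


def _write_metric_tables(out_dir, metrics, evs):
    for cond, m in metrics.items():
        ev = evs[cond]
        pd.DataFrame(
            {
                "trial": np.arange(m.n_trials),
                "onset_sample": ev.sample_indices[: m.n_trials],
                "amplitude_uV": m.amplitude,
                "phase_rad": m.phase,
            }
        ).to_csv(os.path.join(out_dir, f"trial_metrics_{cond}.tsv"), sep="\t", index=False)


def _test_tables(out_dir, metrics):
    amp = amplitude_tests(
        metrics["no_stim"].amplitude,
        metrics["stim_raw"].amplitude,
        metrics["stim_sass"].amplitude,
    )
    pha = {
        "no_stim_vs_stim_raw": wallraff_test(
            metrics["no_stim"].phase, metrics["stim_raw"].phase, sided="one"
        ),
        "stim_raw_vs_stim_sass": wallraff_test(
            metrics["stim_raw"].phase, metrics["stim_sass"].phase, paired=True, sided="one",
            alternative="greater",
        ),
        "no_stim_vs_stim_sass": wallraff_test(
            metrics["no_stim"].phase, metrics["stim_sass"].phase, sided="two"
        ),
    }
    for name, res in (("amplitude_tests", amp), ("phase_tests", pha)):
        rows = [
            {
                "comparison": k,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "sidedness": r.sidedness,
                "paired": r.paired,
                "stars": r.stars,
            }
            for k, r in res.items()
        ]
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    return amp, pha


def _figures(out_dir, no_stim, stim, model, metrics, cfg):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mont = standard_montage_64()
    fs = stim.fs
    tmin, tmax = cfg.trial_window

    # PSDs of the occipital virtual channel, three conditions
    fig, ax = plt.subplots(figsize=(6, 4))
    series = {
        "no stimulation": virtual_channel(no_stim, occipital_set=cfg.occipital_set),
        "stim + SASS": virtual_channel(
            model.P @ stim.eeg_data(), stim.eeg_labels, cfg.occipital_set
        ),
        "stim w/o SASS": virtual_channel(stim, occipital_set=cfg.occipital_set),
    }
    rows = {}
    for label, sig in series.items():
        freqs, psd = welch_psd(sig, fs)
        ax.semilogy(freqs, psd[0], label=label)
        rows[label] = psd[0]
    ax.set_xlim(0, 40)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (uV$^2$/Hz)")
    ax.legend()
    fig.savefig(os.path.join(out_dir, "psd.pdf"))
    plt.close(fig)
    pd.DataFrame({"freq_Hz": freqs, **rows}).to_csv(
        os.path.join(out_dir, "psd.tsv"), sep="\t", index=False
    )

    # log-amplitude topographies
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax_, (cond, rec_, proj) in zip(
        axes,
        (
            ("no_stim", no_stim, None),
            ("stim_sass", stim, model.P),
            ("stim_raw", stim, None),
        ),
    ):
        topo = amplitude_topography(
            rec_, _trial_events(rec_), cfg.band, tmin, tmax, projection=proj
        )
        xy = np.array([mont[l] for l in topo])
        vals = np.log10(list(topo.values()))
        sc = ax_.scatter(xy[:, 0], xy[:, 1], c=vals, cmap="viridis", s=60)
        ax_.set_title(cond)
        ax_.set_aspect("equal")
        ax_.axis("off")
        fig.colorbar(sc, ax=ax_, label="log10 amplitude (uV)")
        pd.DataFrame({"channel": list(topo), "amplitude_uV": list(topo.values())}).to_csv(
            os.path.join(out_dir, f"topography_{cond}.tsv"), sep="\t", index=False
        )
    fig.savefig(os.path.join(out_dir, "topographies.pdf"))
    plt.close(fig)

    # eigenvalue spectrum and leading spatial patterns
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].semilogy(np.arange(1, model.n_channels + 1), model.eigenvalues, "o-")
    axes[0].set_xlabel("component")
    axes[0].set_ylabel("power ratio stim / no-stim")
    xy = np.array([mont[l] for l in model.channel_labels])
    pat = model.patterns[:, 0]
    sc = axes[1].scatter(xy[:, 0], xy[:, 1], c=pat, cmap="RdBu_r", s=60)
    axes[1].set_title("pattern of component 1")
    axes[1].set_aspect("equal")
    axes[1].axis("off")
    fig.colorbar(sc, ax=axes[1])
    fig.savefig(os.path.join(out_dir, "eigenspectrum.pdf"))
    plt.close(fig)

    # single-trial amplitudes and phases per condition
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for cond in CONDITIONS:
        axes[0].plot(metrics[cond].amplitude, ".", label=cond, alpha=0.6)
        axes[1].plot(metrics[cond].phase, ".", label=cond, alpha=0.6)
    axes[0].set_yscale("log")
    axes[0].set_ylabel("single-trial amplitude (uV)")
    axes[1].set_ylabel("phase rel. flicker (rad)")
    for ax_ in axes:
        ax_.set_xlabel("trial")
        ax_.legend(fontsize=7)
    fig.savefig(os.path.join(out_dir, "single_trials.pdf"))
    plt.close(fig)


def run_analyze(cfg: RunConfig, recordings=None):
    """Full three-condition analysis of a session pair.

    ``recordings`` may pass ``(no_stim, stim)`` Recording objects directly;
    otherwise the BrainVision paths in ``cfg`` are read.  Returns a dict
    with the fitted model, per-condition trial metrics and test results.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    no_stim, stim = recordings if recordings is not None else _load_pair(cfg)
    ev0, ev1 = _trial_events(no_stim), _trial_events(stim)
    model = sass_fit(no_stim, stim, cfg.band)
    models = (
        sass_multiband(no_stim, stim, cfg.centers, cfg.band.half_width)
        if cfg.centers
        else []
    )
    metrics = _condition_metrics(cfg, no_stim, stim, model, ev0, ev1)
    evs = {"no_stim": ev0, "stim_sass": ev1, "stim_raw": ev1}
    _write_metric_tables(cfg.out_dir, metrics, evs)
    amp, pha = _test_tables(cfg.out_dir, metrics)
    pd.DataFrame(
        {"component": np.arange(1, model.n_channels + 1), "eigenvalue": model.eigenvalues}
    ).to_csv(os.path.join(cfg.out_dir, "eigenvalues.tsv"), sep="\t", index=False)
    pd.DataFrame(model.patterns, index=model.channel_labels).to_csv(
        os.path.join(cfg.out_dir, "sass_patterns.tsv"), sep="\t"
    )
    if cfg.figures:
        _figures(cfg.out_dir, no_stim, stim, model, metrics, cfg)
    summary = {
        "k_reject": model.k_reject,
        "n_trials": {c: metrics[c].n_trials for c in CONDITIONS},
        "plv": {c: plv(metrics[c].phase) for c in CONDITIONS},
        "mean_amplitude_uV": {c: float(metrics[c].amplitude.mean()) for c in CONDITIONS},
    }
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    _manifest(
        cfg.out_dir,
        cfg.seed,
        {"band": cfg.band.__dict__, "crossval": cfg.crossval},
        inputs=[p + ext for p in (cfg.no_stim_path, cfg.stim_path) if p
                for ext in ("",)],
    )
    return {
        "model": model,
        "multiband": models,
        "metrics": metrics,
        "amplitude_tests": amp,
        "phase_tests": pha,
        "summary": summary,
    }


def _truncate(rec: Recording, n_samples: int) -> Recording:
    return Recording(
        list(rec.channel_labels),
        list(rec.channel_types),
        rec.fs,
        rec.data[:, :n_samples],
        montage=dict(rec.montage),
    )


def run_crossval(cfg: RunConfig, recordings=None):
    """Fit SASS on the first half of trials, evaluate on the second half.

    The split point is the continuous-recording midpoint between trial
    ``n/2`` and trial ``n/2 + 1``; covariances use only data before it.
    Returns PLV and mean amplitude per condition on held-out trials.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    no_stim, stim = recordings if recordings is not None else _load_pair(cfg)
    ev0, ev1 = _trial_events(no_stim), _trial_events(stim)
    if min(len(ev0), len(ev1)) < 20:
        raise DegenerateDataError("cross-validation needs at least 20 trials")
    trial_samp = int(round((cfg.trial_window[1] - cfg.trial_window[0]) * stim.fs))

    def split_point(ev):
        mid = len(ev) // 2
        end_first = ev.sample_indices[mid - 1] + trial_samp
        return (end_first + ev.sample_indices[mid]) // 2, mid

    s0, mid0 = split_point(ev0)
    s1, mid1 = split_point(ev1)
    model = sass_fit(_truncate(no_stim, s0), _truncate(stim, s1), cfg.band)
    ev0_b = EventSeries(ev0.sample_indices[mid0:], no_stim.fs)
    ev1_b = EventSeries(ev1.sample_indices[mid1:], stim.fs)
    metrics = _condition_metrics(cfg, no_stim, stim, model, ev0_b, ev1_b)
    evs = {"no_stim": ev0_b, "stim_sass": ev1_b, "stim_raw": ev1_b}
    _write_metric_tables(cfg.out_dir, metrics, evs)
    summary = {
        "k_reject": model.k_reject,
        "split_sample": {"no_stim": int(s0), "stim": int(s1)},
        "plv": {c: plv(metrics[c].phase) for c in CONDITIONS},
        "mean_amplitude_uV": {c: float(metrics[c].amplitude.mean()) for c in CONDITIONS},
    }
    with open(os.path.join(cfg.out_dir, "crossval_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    _manifest(cfg.out_dir, cfg.seed, {"band": cfg.band.__dict__, "crossval": True})
    return {"model": model, "metrics": metrics, "summary": summary}


def run_heartbeat(
    cfg: RunConfig,
    recording: Recording | None = None,
    n_perm: int = 1000,
    picks=None,
):
    """R-peak-locked artifact-envelope analysis of the stimulation session.

    Operates on the raw (uncleaned) stimulation data, since the artifact
    itself is the object under study.  ``picks`` restricts the channel set
    (labels) to bound runtime.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    rec = recording if recording is not None else read_brainvision(cfg.stim_path)
    if picks is not None:
        keep = [i for i, l in enumerate(rec.channel_labels)
                if l in picks or rec.channel_types[i] != "eeg"]
        rec = Recording(
            [rec.channel_labels[i] for i in keep],
            [rec.channel_types[i] for i in keep],
            rec.fs,
            rec.data[keep],
        )
    peaks = detect_r_peaks(rec.ecg(), rec.fs)
    result = permutation_pvalues(rec, peaks, n_perm=n_perm, seed=cfg.seed)
    df = pd.DataFrame(result.mean_envelope.T, columns=result.channel_labels)
    df.insert(0, "lag_s", result.lags)
    df.to_csv(os.path.join(cfg.out_dir, "heartbeat_envelope.tsv"), sep="\t", index=False)
    dp = pd.DataFrame(result.p_values.T, columns=result.channel_labels)
    dp.insert(0, "lag_s", result.lags)
    dp.to_csv(os.path.join(cfg.out_dir, "heartbeat_pvalues.tsv"), sep="\t", index=False)
    _manifest(cfg.out_dir, cfg.seed, {"n_perm": n_perm, "analysis": "heartbeat"})
    return result
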
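"""HDF5 serialization of session bundles and ground truth.

Layout: ``/units`` (ragged spike times + metadata), ``/emg`` (1 kHz
envelopes), ``/trials`` (CSV-mirrored table), ``/truth`` (generator ground
truth, optional).
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .latents import LatentSet
from .session import GroundTruth, SessionBundle

_TRIAL_COLUMNS = [
    "cue_ms",
    "go_ms",
    "reach_onset_ms",
    "grasp_ms",
    "spout",
    "success",
    "light",
]


def save_session(
    path: str, bundle: SessionBundle, truth: GroundTruth | None = None
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("units")
        flat = np.concatenate([s for s in bundle.spike_times]) if bundle.n_units else np.empty(0)
        counts = np.array([s.size for s in bundle.spike_times], dtype=np.int64)
        g.create_dataset("spike_times_s", data=flat)
        g.create_dataset("spike_counts", data=counts)
        g.create_dataset(
            "region", data=np.array([r.encode() for r in bundle.unit_region])
        )
        g.create_dataset("depth_um", data=bundle.unit_depth)
        g.create_dataset("width_ms", data=bundle.unit_width)
        g.create_dataset("peak_sign", data=bundle.unit_peak_sign)

        f.create_dataset("emg/envelope", data=bundle.emg)
        f["emg"].attrs["fs_hz"] = 1000

        gt = f.create_group("trials")
        for col in _TRIAL_COLUMNS:
            gt.create_dataset(col, data=bundle.trials[col].to_numpy())
        f.attrs["duration_s"] = bundle.duration_s

        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("delays_ms", data=truth.delays_ms)
            tg.create_dataset("reach_onsets_ms", data=truth.reach_onsets_ms)
            lat = truth.latents
            lg = tg.create_group("latents")
            for name in ("time_ms", "across_a", "across_b", "within_a", "within_b",
                         "delays_ms", "timescales_ms"):
                lg.create_dataset(name, data=getattr(lat, name))
            for region, prof in truth.suppression.items():
                tg.create_dataset(f"suppression_{region}", data=prof)
            if truth.light_trials is not None:
                tg.create_dataset("light_trials", data=truth.light_trials)
            for key, mat in truth.loadings.items():
                tg.create_dataset(f"loadings/{key}", data=mat)
            for region, b in truth.baselines.items():
                tg.create_dataset(f"baselines/{region}", data=b)


def load_session(path: str) -> tuple[SessionBundle, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        g = f["units"]
        counts = g["spike_counts"][()]
        flat = g["spike_times_s"][()]
        edges = np.concatenate([[0], np.cumsum(counts)])
        spike_times = [flat[edges[i] : edges[i + 1]] for i in range(counts.size)]
        trials = pd.DataFrame({c: f["trials"][c][()] for c in _TRIAL_COLUMNS})
        bundle = SessionBundle(
            spike_times=spike_times,
            unit_region=np.array([r.decode() for r in g["region"][()]]),
            unit_depth=g["depth_um"][()],
            unit_width=g["width_ms"][()],
            unit_peak_sign=g["peak_sign"][()],
            emg=f["emg/envelope"][()],
            trials=trials,
            duration_s=float(f.attrs["duration_s"]),
        )
        truth = None
        if "truth" in f:
            tg = f["truth"]
            lg = tg["latents"]
            latents = LatentSet(**{k: lg[k][()] for k in lg.keys()})
            suppression = {
                key.split("_", 1)[1]: tg[key][()]
                for key in tg.keys()
                if key.startswith("suppression_")
            }
            truth = GroundTruth(
                latents=latents,
                delays_ms=tg["delays_ms"][()],
                couplings=[],
                reach_onsets_ms=tg["reach_onsets_ms"][()],
                loadings={k: tg["loadings"][k][()] for k in tg["loadings"].keys()}
                if "loadings" in tg
                else {},
                baselines={k: tg["baselines"][k][()] for k in tg["baselines"].keys()}
                if "baselines" in tg
                else {},
                suppression=suppression,
                light_trials=tg["light_trials"][()] if "light_trials" in tg else None,
            )
    return bundle, truth
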
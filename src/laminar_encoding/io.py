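"""File formats for the pipeline's artifacts.

Sounds go to 16-bit PCM WAV (plus a CSV of category/set labels), event
designs to CSV, numerical arrays (populations, BOLD runs, features,
betas, encoding fits) to HDF5 with documented dataset names, and configs
and summaries to YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .audio_features import FeatureMatrix
from .synthetic_data import (
    BoldTimeseries,
    DepthGrid,
    EventDesign,
    GroundTruthPopulation,
    SoundSet,
)

WAV_SCALE = 0.25  # shared amplitude headroom so equalised RMS survives I/O


def save_sounds(sounds: SoundSet, directory: str | Path) -> None:
    """Write one WAV per sound plus ``sounds.csv`` with the labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = np.abs(sounds.waveforms).max()
    gain = WAV_SCALE / peak if peak > 0 else 1.0
    for i, wave in enumerate(sounds.waveforms):
        data = np.clip(wave * gain, -1, 1)
        wavfile.write(
            directory / f"sound_{i:03d}.wav",
            sounds.sample_rate,
            (data * 32767).astype(np.int16),
        )
    pd.DataFrame(
        {
            "sound_id": sounds.sound_id,
            "category": sounds.category,
            "set_id": sounds.set_id,
            "wav_gain": gain,
        }
    ).to_csv(directory / "sounds.csv", index=False)


def load_sounds(directory: str | Path) -> SoundSet:
    directory = Path(directory)
    meta = pd.read_csv(directory / "sounds.csv")
    waves = []
    sr = None
    for i in meta["sound_id"]:
        sr, data = wavfile.read(directory / f"sound_{i:03d}.wav")
        waves.append(data.astype(float) / 32767 / meta["wav_gain"].iloc[0])
    return SoundSet(
        waveforms=np.asarray(waves),
        category=meta["category"].to_numpy(dtype=object).astype(str),
        set_id=meta["set_id"].to_numpy(),
        sound_id=meta["sound_id"].to_numpy(),
        sample_rate=int(sr),
    )


def designs_to_csv(designs: list[EventDesign], path: str | Path) -> None:
    rows = []
    for d in designs:
        for onset, sid, sil, rep in zip(d.onsets, d.sound_id, d.is_silent, d.is_repeat):
            rows.append(
                {
                    "run_id": d.run_id,
                    "set_id": d.set_id,
                    "onset_TR": int(onset),
                    "sound_id": int(sid),
                    "is_silent": bool(sil),
                    "is_repeat": bool(rep),
                    "n_volumes": d.n_volumes,
                    "tr_s": d.tr_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def designs_from_csv(path: str | Path) -> list[EventDesign]:
    df = pd.read_csv(path)
    designs = []
    for run_id, g in df.groupby("run_id", sort=True):
        designs.append(
            EventDesign(
                run_id=int(run_id),
                set_id=int(g["set_id"].iloc[0]),
                onsets=g["onset_TR"].to_numpy(),
                sound_id=g["sound_id"].to_numpy(),
                is_silent=g["is_silent"].to_numpy(dtype=bool),
                is_repeat=g["is_repeat"].to_numpy(dtype=bool),
                n_volumes=int(g["n_volumes"].iloc[0]),
                tr_s=float(g["tr_s"].iloc[0]),
            )
        )
    return designs


def save_population(
    pop: GroundTruthPopulation, grid: DepthGrid, path: str | Path
) -> None:
    """HDF5 layout: /population/{...}, /grid/{mrc,pac_mask,depths,voxel_index}."""
    with h5py.File(path, "w") as f:
        g = f.create_group("population")
        g.create_dataset("grid_index", data=pop.grid_index)
        g.create_dataset("depth_index", data=pop.depth_index)
        g.create_dataset("depth", data=pop.depth)
        g.create_dataset("region", data=np.char.encode(pop.region.astype(str)))
        g.create_dataset(
            "tuning_model", data=np.char.encode(pop.tuning_model.astype(str))
        )
        g.create_dataset("true_weights", data=pop.true_weights)
        g.create_dataset("snr", data=pop.snr)
        g.create_dataset("hrf_peak_s", data=pop.hrf_peak_s)
        g.create_dataset("hrf_undershoot", data=pop.hrf_undershoot)
        g.attrs["scenario"] = pop.scenario
        gg = f.create_group("grid")
        gg.create_dataset("mrc", data=grid.mrc)
        gg.create_dataset("pac_mask", data=grid.pac_mask)
        gg.create_dataset("depths", data=grid.depths)
        gg.create_dataset("voxel_index", data=grid.voxel_index)
        if grid.pref_octave is not None:
            gg.create_dataset("pref_octave", data=grid.pref_octave)


def load_population(path: str | Path) -> tuple[GroundTruthPopulation, DepthGrid]:
    with h5py.File(path, "r") as f:
        g = f["population"]
        pop = GroundTruthPopulation(
            grid_index=g["grid_index"][:],
            depth_index=g["depth_index"][:],
            depth=g["depth"][:],
            region=np.char.decode(g["region"][:]).astype(object),
            tuning_model=np.char.decode(g["tuning_model"][:]).astype(object),
            true_weights=g["true_weights"][:],
            snr=g["snr"][:],
            hrf_peak_s=g["hrf_peak_s"][:],
            hrf_undershoot=g["hrf_undershoot"][:],
            scenario=str(g.attrs["scenario"]),
        )
        gg = f["grid"]
        grid = DepthGrid(
            mrc=gg["mrc"][:],
            pac_mask=gg["pac_mask"][:].astype(bool),
            depths=gg["depths"][:],
            voxel_index=gg["voxel_index"][:],
            pref_octave=gg["pref_octave"][:] if "pref_octave" in gg else None,
        )
    return pop, grid


def save_bold(bold: BoldTimeseries, path: str | Path) -> None:
    """HDF5 layout: /run_000, /run_001, ... plus tr_s and noise params."""
    with h5py.File(path, "w") as f:
        for i, run in enumerate(bold.runs):
            f.create_dataset(f"run_{i:03d}", data=run)
        f.attrs["tr_s"] = bold.tr_s
        f.attrs["params"] = json.dumps(bold.params)


def load_bold(path: str | Path) -> BoldTimeseries:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f.keys() if k.startswith("run_"))
        runs = [f[k][:] for k in keys]
        return BoldTimeseries(
            runs=runs,
            tr_s=float(f.attrs["tr_s"]),
            params=json.loads(f.attrs.get("params", "{}")),
        )


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """HDF5 layout: /values plus per-label datasets under /labels."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fm.values)
        f.attrs["model_tag"] = fm.model_tag
        if fm.sound_ids is not None:
            f.create_dataset("sound_ids", data=fm.sound_ids)
        lab = f.create_group("labels")
        for k, v in fm.labels.items():
            lab.create_dataset(k, data=np.asarray(v))


def load_features(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        labels = {k: f["labels"][k][:] for k in f["labels"]}
        return FeatureMatrix(
            values=f["values"][:],
            model_tag=str(f.attrs["model_tag"]),
            labels=labels,
            sound_ids=f["sound_ids"][:] if "sound_ids" in f else None,
        )


def features_to_csv(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.values)
    if fm.sound_ids is not None:
        df.insert(0, "sound_id", fm.sound_ids)
    df.to_csv(path, index=False)


def save_config(config_dict: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_dict, f, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(summary, f, sort_keys=True, indent=2)
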
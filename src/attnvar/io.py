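"""Session bundle serialization.

A simulated session is written as a directory with the trial schedule and
behavior as CSV, arrays (spikes, eye traces, LFP, sequences) in an HDF5
container, results tables as CSV, and a JSON provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .pipeline import SessionData, SessionResults

__all__ = ["save_session_bundle", "load_spikes", "save_results"]


def save_session_bundle(data: SessionData, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.trials.to_csv(out / "trials.csv")
    with h5py.File(out / "arrays.h5", "w") as f:
        g = f.create_group("spikes")
        for i, trains in enumerate(data.spikes):
            gi = g.create_group(f"trial{i:05d}")
            for u, t in enumerate(trains):
                gi.create_dataset(f"unit{u:03d}", data=np.asarray(t))
        g = f.create_group("sequences")
        for i, codes in enumerate(data.rf_codes):
            if codes is not None:
                g.create_dataset(f"trial{i:05d}", data=codes)
        f.create_dataset("lfp", data=data.lfp)
        f.create_dataset("pre_counts", data=data.pre_counts)
        g = f.create_group("eye")
        for i, xy in enumerate(data.eye_traces):
            if xy is not None:
                g.create_dataset(f"trial{i:05d}", data=xy.astype(np.float32))
    (out / "provenance.json").write_text(
        json.dumps(data.config.provenance(), indent=2))
    (out / "ground_truth.json").write_text(
        json.dumps({k: v for k, v in data.ground_truth.items() if k != "eye_events"},
                   default=str, indent=2))
    return out


def load_spikes(bundle_dir: str | Path):
    """Load the spike container from a bundle (trial -> unit -> times)."""
    with h5py.File(Path(bundle_dir) / "arrays.h5", "r") as f:
        g = f["spikes"]
        return [
            [np.asarray(g[trial][unit]) for unit in sorted(g[trial])]
            for trial in sorted(g)
        ]


def save_results(res: SessionResults, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.behavior_summary.to_csv(out / "behavior.csv")
    res.tuning.to_csv(out / "tuning.csv")
    res.modulation.to_csv(out / "modulation.csv")
    res.rsc.to_csv(out / "rsc.csv", index=False)
    res.fano.to_csv(out / "fano.csv", index=False)
    res.layers.to_csv(out / "layers.csv", index=False)
    rows = []
    for cond, (tau, curve) in res.r_ccg.items():
        rows.append(pd.DataFrame(dict(condition=cond, tau_ms=tau, r_ccg=curve)))
    if rows:
        pd.concat(rows).to_csv(out / "r_ccg.csv", index=False)
    summary = dict(
        provenance=res.provenance, included=res.included,
        inclusion_reasons=res.inclusion_reasons, mean_rate_hz=res.mean_rate_hz,
        rate_by_condition=res.rate_by_condition, contrast_1000=res.contrast_1000,
        csd_sink_channel=res.csd_sink_channel,
        thresholds={c: f.threshold_50 for c, f in res.thresholds.items()},
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return out
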
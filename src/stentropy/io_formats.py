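"""Read/write movies, metadata sidecars, result tables and figures.

Interchange formats: multi-frame TIFF for movies (one file per channel, one
frame per time sample, dtype preserved so integer camera data round-trips
exactly), a YAML sidecar for acquisition metadata and ground truth, CSV for
tables, PNG for figures.  The frame interval is never guessed: a sidecar that
does not declare it is a hard error.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
import yaml

from .cubes import SpacetimeCube
from .entropy import EntropyResult, EntropyTrace
from .episodes import Episode

_CSV_FLOAT = "%.10g"


def write_recording(recording, out_dir) -> dict[str, Path]:
    """Write a LabeledRecording: vm.tif + cai.tif + sidecar.yaml + truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vm_path = out / "vm.tif"
    cai_path = out / "cai.tif"
    tifffile.imwrite(vm_path, recording.vm_cube.values)
    tifffile.imwrite(cai_path, recording.cai_cube.values)
    sidecar = {
        "frame_interval_ms": float(recording.vm_cube.frame_interval),
        "channels": {"Vm": vm_path.name, "Cai": cai_path.name},
        "pacing_cl_ms": float(recording.spec.pacing_cl) if recording.spec else None,
        "spec": asdict(recording.spec) if recording.spec else None,
        "truth_episodes": [
            {
                "onset_frame": e.onset_frame,
                "onset_row": e.onset_pixel[0],
                "onset_col": e.onset_pixel[1],
                "duration_ms": e.duration,
                "label": e.label,
                "cycle_length_mean_ms": e.cycle_length_mean,
                "cycle_length_sd_ms": e.cycle_length_sd,
            }
            for e in recording.truth_episodes
        ],
    }
    sidecar_path = out / "sidecar.yaml"
    sidecar_path.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    truth_path = out / "truth_episodes.csv"
    pd.DataFrame(sidecar["truth_episodes"]).to_csv(
        truth_path, index=False, float_format=_CSV_FLOAT
    )
    return {"vm": vm_path, "cai": cai_path, "sidecar": sidecar_path, "truth": truth_path}


def read_sidecar(sidecar_path) -> dict:
    sidecar = yaml.safe_load(Path(sidecar_path).read_text())
    if not isinstance(sidecar, dict) or "frame_interval_ms" not in sidecar:
        raise ValueError(
            f"sidecar {sidecar_path} does not declare frame_interval_ms; "
            "the frame interval is never guessed"
        )
    return sidecar


def read_recording(vm_path, cai_path, sidecar_path) -> tuple[SpacetimeCube, SpacetimeCube]:
    """Read the two channel movies; shapes and frame counts must agree."""
    sidecar = read_sidecar(sidecar_path)
    fi = float(sidecar["frame_interval_ms"])
    vm = tifffile.imread(vm_path)
    cai = tifffile.imread(cai_path)
    if vm.shape != cai.shape:
        raise ValueError(
            f"channel shape mismatch: Vm {vm.shape} vs Cai {cai.shape}"
        )
    return (
        SpacetimeCube(vm, fi, channel="Vm"),
        SpacetimeCube(cai, fi, channel="Cai"),
    )


def episodes_frame(episodes: list[Episode], frame_interval: float) -> pd.DataFrame:
    cols = [
        "onset_ms", "onset_row", "onset_col", "duration_ms", "label",
        "cycle_length_mean_ms", "cycle_length_sd_ms", "e_vm", "e_ca", "e_d",
    ]
    rows = [
        {
            "onset_ms": e.onset_frame * frame_interval,
            "onset_row": e.onset_pixel[0],
            "onset_col": e.onset_pixel[1],
            "duration_ms": e.duration,
            "label": e.label,
            "cycle_length_mean_ms": e.cycle_length_mean,
            "cycle_length_sd_ms": e.cycle_length_sd,
            "e_vm": e.e_vm,
            "e_ca": e.e_ca,
            "e_d": e.e_d,
        }
        for e in episodes
    ]
    return pd.DataFrame(rows, columns=cols)


def trace_frame(trace: EntropyTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_ms": trace.times_ms,
            "e_vm": trace.e_vm_series,
            "e_ca": trace.e_ca_series,
            "e_d": trace.e_d_series,
        }
    )


def write_results(
    episodes: list[Episode],
    trace: EntropyTrace | None,
    out_dir,
    frame_interval: float,
    figures: bool = True,
) -> dict[str, Path]:
    """Write per-episode and running-entropy CSV tables (+ PNG figure).

    CSVs are byte-stable for identical inputs (fixed float formatting).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ep_path = out / "episodes.csv"
    episodes_frame(episodes, frame_interval).to_csv(
        ep_path, index=False, float_format=_CSV_FLOAT
    )
    paths["episodes"] = ep_path
    if trace is not None:
        tr_path = out / "running_entropy.csv"
        trace_frame(trace).to_csv(tr_path, index=False, float_format=_CSV_FLOAT)
        paths["trace"] = tr_path
        if figures:
            fig_path = out / "running_entropy.png"
            fig, ax = plt.subplots(figsize=(7, 3.5))
            ax.plot(trace.times_ms, trace.e_vm_series, label="E Vm", color="k")
            ax.plot(trace.times_ms, trace.e_ca_series, label="E Cai", color="r")
            ax.plot(trace.times_ms, trace.e_d_series, label="E_d", color="b", ls="--")
            ax.set_xlabel("window start (ms)")
            ax.set_ylabel("entropy (nats)")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(fig_path, dpi=120)
            plt.close(fig)
            paths["figure"] = fig_path
    return paths
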
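"""Session persistence: EDF traces with CSV hypnogram and JSON ground truth.

A session directory contains:

* ``session.edf``       — the six channels in microvolts, one-second records;
* ``hypnogram.csv``     — columns start_s, duration_s, state;
* ``ground_truth.json`` — burst schedule, seed, montage geometry, medium.

The sidecars are optional on read: a session without them is returned with a
warning and ``hypnogram`` / ``bursts`` set to ``None``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._edf import read_edf, write_edf
from .forward import ElectrodePair
from .simulate import (
    BurstSpec,
    ElectrodeMontage,
    Hypnogram,
    RecordingSession,
)

__all__ = ["write_session", "read_session"]

EDF_NAME = "session.edf"
HYPNOGRAM_NAME = "hypnogram.csv"
TRUTH_NAME = "ground_truth.json"

_V_TO_UV = 1e6


def _montage_to_dict(montage: ElectrodeMontage) -> dict:
    return {
        "pairs": {
            area: {
                "midpoint": pair.midpoint.tolist(),
                "axis": pair.axis.tolist(),
                "half_separation": pair.half_separation,
            }
            for area, pair in montage.pairs.items()
        },
        "reference": montage.reference.tolist(),
        "reference_factor": montage.reference_factor,
    }


def _montage_from_dict(d: dict) -> ElectrodeMontage:
    return ElectrodeMontage(
        pairs={
            area: ElectrodePair(
                np.array(p["midpoint"]), np.array(p["axis"]), p["half_separation"]
            )
            for area, p in d["pairs"].items()
        },
        reference=np.array(d["reference"]),
        reference_factor=d.get("reference_factor", 10.0),
    )


def write_session(session: RecordingSession, directory) -> Path:
    """Write a session (EDF + sidecars) into ``directory``; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    write_edf(
        directory / EDF_NAME,
        session.data * _V_TO_UV,
        session.fs,
        session.labels,
        physical_dimension="uV",
    )

    if session.hypnogram is not None:
        session.hypnogram.to_frame().to_csv(directory / HYPNOGRAM_NAME, index=False)

    truth = {
        "seed": session.seed,
        "fs": session.fs,
        "labels": list(session.labels),
        "montage": _montage_to_dict(session.montage),
        "bursts": [
            {
                "onset": b.onset,
                "duration": b.duration,
                "frequency": b.frequency,
                "areas": list(b.areas),
                "delay": b.delay,
            }
            for b in (session.bursts or [])
        ],
    }
    with open(directory / TRUTH_NAME, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return directory


def read_session(directory) -> RecordingSession:
    """Read a session directory back into a :class:`RecordingSession`.

    Missing sidecars degrade gracefully: the traces are always loaded, but
    the hypnogram / ground truth fields are ``None`` with a warning.
    """
    directory = Path(directory)
    data_uv, fs, labels = read_edf(directory / EDF_NAME)

    hypnogram: Optional[Hypnogram] = None
    hyp_path = directory / HYPNOGRAM_NAME
    if hyp_path.exists():
        hypnogram = Hypnogram.from_frame(pd.read_csv(hyp_path))
    else:
        warnings.warn(f"no {HYPNOGRAM_NAME} sidecar in {directory}; "
                      "session loaded without state labels")

    bursts = None
    montage = None
    seed = None
    truth_path = directory / TRUTH_NAME
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        seed = truth.get("seed")
        montage = _montage_from_dict(truth["montage"])
        bursts = [
            BurstSpec(
                b["onset"], b["duration"], b["frequency"],
                tuple(b["areas"]), b.get("delay", 0.0),
            )
            for b in truth.get("bursts", [])
        ]
    else:
        warnings.warn(f"no {TRUTH_NAME} sidecar in {directory}; "
                      "session loaded without ground truth")

    if montage is None:
        # montage geometry lives in the ground-truth sidecar; without it fall
        # back to the default so RR/DR derivation still works by label
        from .simulate import default_montage
        montage = default_montage()

    return RecordingSession(
        data=data_uv / _V_TO_UV,
        labels=tuple(labels),
        fs=fs,
        montage=montage,
        hypnogram=hypnogram,
        bursts=bursts,
        seed=seed,
    )
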
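"""HDF5 session container and tabular export helpers.

Sessions are stored as: ``/data`` (channels × samples, float64, tesla),
``/events`` (int64 sample indices), root attributes ``sample_rate``,
``subject_id``, ``seed``, and an ``/array`` group mirroring the TSV
sensor schema (name, x, y, z, ox, oy, oz, is_reference).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from opmpipe.forward import SensorArray
from opmpipe.simulate import LONG_MNS, SHORT_MNS, ProtocolSpec, RawSession

_PROTOCOLS = {"short_mns": SHORT_MNS, "long_mns": LONG_MNS}


def save_session(session: RawSession, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=session.data, dtype="float64")
        f.create_dataset("events", data=session.events, dtype="int64")
        f.attrs["sample_rate"] = float(session.sample_rate)
        f.attrs["subject_id"] = session.subject_id
        f.attrs["seed"] = int(session.seed)
        if session.protocol is not None:
            f.attrs["protocol"] = session.protocol.name
        g = f.create_group("array")
        g.create_dataset("name", data=np.array(session.array.names, dtype="S32"))
        g.create_dataset("position", data=session.array.positions)
        g.create_dataset("orientation", data=session.array.orientations)
        g.create_dataset("is_reference",
                         data=session.array.is_reference.astype("int8"))


def load_session(path) -> RawSession:
    with h5py.File(path, "r") as f:
        g = f["array"]
        array = SensorArray(
            [n.decode() for n in g["name"][()]],
            g["position"][()],
            g["orientation"][()],
            g["is_reference"][()].astype(bool),
        )
        protocol: ProtocolSpec | None = None
        if "protocol" in f.attrs:
            protocol = _PROTOCOLS.get(str(f.attrs["protocol"]))
        return RawSession(
            f["data"][()],
            float(f.attrs["sample_rate"]),
            f["events"][()],
            array,
            str(f.attrs["subject_id"]),
            int(f.attrs["seed"]),
            protocol,
        )


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
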
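"""On-disk container for stimulus-response recordings.

HDF5 layout (NPZ fallback chosen by file extension):

    /stimulus/spec       float64 [F x T]
    /stimulus/freqs_hz   float64 [F]
    /stimulus/segments   int64   [n x 2]   half-open, 0-based
    /response/spikes     uint8   [T]
    attrs: dt_s          float   (root attribute)

Round trips are lossless for all fields.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .datamodel import SpikeTrain, StimulusEnsemble

__all__ = ["read_recording", "write_recording"]


def _is_npz(path: Path) -> bool:
    return path.suffix.lower() == ".npz"


def write_recording(path, ens: StimulusEnsemble, spikes: SpikeTrain) -> None:
    """Write a paired recording; stimulus and spikes must share dt and T."""
    if abs(ens.dt_s - spikes.dt_s) > 1e-12:
        raise ValueError(
            f"dt mismatch: stimulus {ens.dt_s} s vs spikes {spikes.dt_s} s"
        )
    if spikes.n_bins != ens.n_bins:
        raise ValueError(
            f"spike vector length {spikes.n_bins} != stimulus bins {ens.n_bins}"
        )
    path = Path(path)
    segments = np.asarray(ens.segments, dtype=np.int64).reshape(-1, 2)
    if _is_npz(path):
        np.savez(
            path,
            spec=ens.spec,
            freqs_hz=ens.freqs_hz,
            segments=segments,
            spikes=spikes.r,
            dt_s=np.float64(ens.dt_s),
        )
        return
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        # track_times=False keeps files byte-identical across reruns
        g.create_dataset("spec", data=ens.spec, track_times=False)
        g.create_dataset("freqs_hz", data=ens.freqs_hz, track_times=False)
        g.create_dataset("segments", data=segments, track_times=False)
        f.create_group("response").create_dataset(
            "spikes", data=spikes.r, track_times=False)
        f.attrs["dt_s"] = float(ens.dt_s)


def read_recording(path) -> tuple[StimulusEnsemble, SpikeTrain]:
    """Read a paired recording written by :func:`write_recording`."""
    path = Path(path)
    if _is_npz(path):
        with np.load(path) as z:
            for name in ("spec", "freqs_hz", "segments", "spikes"):
                if name not in z:
                    raise KeyError(f"missing dataset {name}")
            if "dt_s" not in z:
                raise KeyError("missing attribute dt_s")
            dt = float(z["dt_s"])
            ens = StimulusEnsemble(
                spec=z["spec"], dt_s=dt, freqs_hz=z["freqs_hz"],
                segments=[tuple(s) for s in z["segments"]],
            )
            spikes = SpikeTrain(r=z["spikes"], dt_s=dt)
    else:
        with h5py.File(path, "r") as f:
            for name in ("stimulus/spec", "stimulus/freqs_hz",
                         "stimulus/segments", "response/spikes"):
                if name not in f:
                    raise KeyError(f"missing dataset {name}")
            if "dt_s" not in f.attrs:
                raise KeyError("missing attribute dt_s")
            dt = float(f.attrs["dt_s"])
            ens = StimulusEnsemble(
                spec=f["stimulus/spec"][()],
                dt_s=dt,
                freqs_hz=f["stimulus/freqs_hz"][()],
                segments=[tuple(s) for s in f["stimulus/segments"][()]],
            )
            spikes = SpikeTrain(r=f["response/spikes"][()], dt_s=dt)
    if spikes.n_bins != ens.n_bins:
        raise ValueError(
            f"spike vector length {spikes.n_bins} != stimulus bins {ens.n_bins}"
        )
    return ens, spikes
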
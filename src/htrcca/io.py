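"""HDF5 container for epoch sets and model banks, plus the benchmark adapter.

Container schema (version tag ``htrcca-container-1``): datasets ``/data``
[n_trials x Nc x Ns], ``/labels``, ``/blocks``, ``/freqs``,
``/channel_names``; file attributes ``fs``, ``latency_s``, ``version`` and
an optional JSON ``provenance`` string.  Simulator clean/noise components
round-trip when present.  The import adapter maps the public SSVEP
datasets' MAT-style [channels x samples x targets x blocks] array into the
same :class:`~htrcca.signal_model.EpochSet`, so real recordings can be used
without being required anywhere.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .filter_bank import SubbandSpec
from .signal_model import EpochSet
from .training import ModelBank, StimulusModel

__all__ = [
    "write_container",
    "read_container",
    "import_benchmark_array",
    "save_model_bank",
    "load_model_bank",
]

CONTAINER_VERSION = "htrcca-container-1"
MODEL_VERSION = "htrcca-models-1"


def write_container(path, epochs: EpochSet, provenance: dict | None = None) -> None:
    """Write an epoch set to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["latency_s"] = float(epochs.latency_s)
        if provenance is not None:
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("blocks", data=epochs.blocks)
        f.create_dataset("freqs", data=epochs.freqs)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        if epochs.clean is not None:
            f.create_dataset("clean", data=epochs.clean)
        if epochs.noise is not None:
            f.create_dataset("noise", data=epochs.noise)


def read_container(path) -> EpochSet:
    """Read an epoch set; raises on unknown version or inconsistent shapes."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != CONTAINER_VERSION:
            raise ValueError(f"unknown container version {version!r}")
        required = {"data", "labels", "blocks", "freqs", "channel_names"}
        missing = required - set(f.keys())
        if missing:
            raise ValueError(f"container missing datasets: {sorted(missing)}")
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            labels=f["labels"][()],
            blocks=f["blocks"][()],
            freqs=f["freqs"][()],
            channel_names=[s.decode() for s in f["channel_names"][()]],
            latency_s=float(f.attrs["latency_s"]),
            clean=f["clean"][()] if "clean" in f else None,
            noise=f["noise"][()] if "noise" in f else None,
        )


def import_benchmark_array(
    arr: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    channel_names: list[str],
    latency_s: float,
) -> EpochSet:
    """Adapt a [Nc x Ns x Nf x B] array (public-dataset layout) to an EpochSet."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a [channels x samples x targets x blocks] array")
    nc, ns, nf, nb = arr.shape
    if nf != len(freqs):
        raise ValueError("target axis does not match the frequency table")
    # -> [B, Nf, Nc, Ns] -> [B*Nf, Nc, Ns], block-major trial order
    trials = arr.transpose(3, 2, 0, 1).reshape(nb * nf, nc, ns)
    labels = np.tile(np.arange(nf), nb)
    blocks = np.repeat(np.arange(nb), nf)
    return EpochSet(
        data=trials,
        fs=fs,
        labels=labels,
        blocks=blocks,
        freqs=np.asarray(freqs, dtype=float),
        channel_names=list(channel_names),
        latency_s=latency_s,
    )


def save_model_bank(path, bank: ModelBank) -> None:
    """Persist a trained model bank (filters, templates, bank geometry)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = MODEL_VERSION
        f.attrs["fs"] = bank.fs
        f.attrs["Nh"] = bank.Nh
        f.attrs["n_train"] = bank.n_train
        if bank.provenance:
            f.attrs["provenance"] = json.dumps(bank.provenance, sort_keys=True)
        f.create_dataset("freqs", data=bank.freqs)
        spec_rows = np.array(
            [
                (
                    s.b, s.passband_lo, s.stopband_lo, s.passband_hi,
                    s.stopband_hi, s.passband_ripple, s.stopband_atten,
                )
                for s in bank.specs
            ]
        )
        f.create_dataset("specs", data=spec_rows)
        for n in range(bank.n_stimuli):
            for b in range(1, bank.n_bands + 1):
                m = bank.get(n, b)
                g = f.create_group(f"model/{n}/{b}")
                for name in ("wa", "wb", "wc", "wd", "wt", "template"):
                    g.create_dataset(name, data=getattr(m, name))
                g.attrs["n_train"] = m.n_train
                g.attrs["fn"] = m.fn


def load_model_bank(path) -> ModelBank:
    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != MODEL_VERSION:
            raise ValueError("unknown model-bank version")
        specs = [
            SubbandSpec(
                b=int(r[0]), passband_lo=r[1], stopband_lo=r[2],
                passband_hi=r[3], stopband_hi=r[4],
                passband_ripple=r[5], stopband_atten=r[6],
            )
            for r in f["specs"][()]
        ]
        freqs = f["freqs"][()]
        models = []
        for n in range(len(freqs)):
            per_band = []
            for b in range(1, len(specs) + 1):
                g = f[f"model/{n}/{b}"]
                per_band.append(
                    StimulusModel(
                        stimulus=n,
                        fn=float(g.attrs["fn"]),
                        band=b,
                        wa=g["wa"][()],
                        wb=g["wb"][()],
                        wc=g["wc"][()],
                        wd=g["wd"][()],
                        wt=g["wt"][()],
                        template=g["template"][()],
                        n_train=int(g.attrs["n_train"]),
                    )
                )
            models.append(per_band)
        prov = f.attrs.get("provenance")
        return ModelBank(
            models=models,
            specs=specs,
            freqs=freqs,
            fs=float(f.attrs["fs"]),
            Nh=int(f.attrs["Nh"]),
            n_train=int(f.attrs["n_train"]),
            provenance=json.loads(prov) if prov else {},
        )
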
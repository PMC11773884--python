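"""Checkpoint format: one ``.npz`` archive with a JSON config header.

The archive stores every parameter as a named array plus a ``__header__``
entry holding UTF-8 JSON (config echo + format version).  The loader rebuilds
the network from the stored config and refuses a config mismatch when asked
to load into an existing network.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .model import Network, NetworkConfig, build_network

__all__ = ["save_network", "load_network"]

FORMAT_VERSION = 1


def _named_params(net: Network) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, p in enumerate(net.parameters()):
        out[f"param_{i:04d}_{p.name}"] = p.value
    return out


def save_network(net: Network, path) -> None:
    header = {
        "format_version": FORMAT_VERSION,
        "config": dataclasses.asdict(net.cfg),
    }
    arrays = _named_params(net)
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_network(path, into: Network | None = None) -> Network:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode("utf-8"))
        if header["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {header['format_version']}")
        cfg = NetworkConfig(**header["config"])
        if into is not None:
            if into.cfg != cfg:
                raise ValueError("checkpoint config does not match the target network")
            net = into
        else:
            net = build_network(cfg)
        stored = _named_params(net)
        for key, param_value in stored.items():
            value = archive[key]
            if value.shape != param_value.shape:
                raise ValueError(f"shape mismatch for {key}")
        for key, p in zip(stored, net.parameters()):
            p.value[...] = archive[key].astype(p.value.dtype)
    return net
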
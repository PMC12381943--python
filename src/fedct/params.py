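"""Keyed, layer-structured parameter collections.

A :class:`ParamSet` is an ordered mapping from layer-path names to real
arrays.  It is the unit of federation traffic: clients upload the shared
model's set, the server aggregates sets entrywise, and checkpoints serialise
them losslessly.  Arithmetic is shape- and name-checked so mismatched
architectures fail loudly.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from typing import Iterable

import numpy as np

ROLES = ("sinogram_net", "image_net", "shared", "prompt", "meta", "meta_prompt")


class AggregationError(ValueError):
    """Raised when parameter sets are not name/shape aligned."""


class ParamSet:
    def __init__(self, entries=None, role: str = "shared"):
        self.entries: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.role = role
        if entries:
            for k, v in entries.items():
                self.entries[k] = np.asarray(v)

    # -- container protocol --------------------------------------------------
    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key):
        return self.entries[key]

    def keys(self):
        return self.entries.keys()

    def items(self):
        return self.entries.items()

    def copy(self) -> "ParamSet":
        return ParamSet({k: v.copy() for k, v in self.entries.items()}, self.role)

    @property
    def n_layers(self) -> int:
        return len(self.entries)

    def count_parameters(self) -> int:
        return int(sum(v.size for v in self.entries.values()))

    # -- arithmetic ----------------------------------------------------------
    def _check_aligned(self, other: "ParamSet"):
        if list(self.keys()) != list(other.keys()):
            raise AggregationError("parameter sets have different entry names")
        for k in self.keys():
            if self.entries[k].shape != other.entries[k].shape:
                raise AggregationError(
                    f"shape mismatch at {k!r}: "
                    f"{self.entries[k].shape} vs {other.entries[k].shape}")

    def add(self, other: "ParamSet") -> "ParamSet":
        self._check_aligned(other)
        return ParamSet({k: self.entries[k] + other.entries[k]
                         for k in self.keys()}, self.role)

    def scale(self, c: float) -> "ParamSet":
        return ParamSet({k: v * c for k, v in self.entries.items()}, self.role)

    def allclose(self, other: "ParamSet", **kw) -> bool:
        self._check_aligned(other)
        return all(np.allclose(self.entries[k], other.entries[k], **kw)
                   for k in self.keys())

    def identical(self, other: "ParamSet") -> bool:
        self._check_aligned(other)
        return all(np.array_equal(self.entries[k], other.entries[k])
                   for k in self.keys())

    # -- serialisation -------------------------------------------------------
    def save(self, path):
        np.savez(path, __role__=np.array(self.role),
                 __order__=np.array(json.dumps(list(self.keys()))),
                 **{k: v for k, v in self.entries.items()})

    @classmethod
    def load(cls, path) -> "ParamSet":
        with np.load(path) as z:
            role = str(z["__role__"])
            order = json.loads(str(z["__order__"]))
            return cls({k: z[k] for k in order}, role)


def count_parameters(p: ParamSet) -> int:
    """Total number of scalar parameters in a set."""
    return p.count_parameters()


def weighted_sum(sets: Iterable[ParamSet], weights: Iterable[float]) -> ParamSet:
    sets = list(sets)
    weights = list(weights)
    out = sets[0].scale(weights[0])
    for s, w in zip(sets[1:], weights[1:]):
        out = out.add(s.scale(w))
    return out
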
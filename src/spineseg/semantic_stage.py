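"""Phase 1: semantic segmentation as a pluggable backend contract.

A trained patch-wise network is out of scope here; the backend contract
documents where such a model plugs in, and phantom-backed oracle/noisy
backends satisfy it for testing.  ``segment_semantic`` validates every
backend output (grid congruence and scheme codes) before phase 2 sees it.
"""

from __future__ import annotations

from importlib.metadata import entry_points
from typing import Callable, Mapping, Protocol, runtime_checkable

import numpy as np

from .label_scheme import BACKGROUND, SCHEME
from .phantom import CorruptionSpec, corrupt_mask
from .volume_io import AnatomicalVolume

__all__ = [
    "SemanticBackend",
    "BackendContractError",
    "OracleSemanticBackend",
    "NoisySemanticBackend",
    "load_external_backend",
    "segment_semantic",
    "validate_semantic_mask",
]


class BackendContractError(ValueError):
    """A backend violated the semantic-output contract."""


@runtime_checkable
class SemanticBackend(Protocol):
    """Callable contract: image volume in, semantic mask on the same grid out."""

    def __call__(self, image: AnatomicalVolume) -> AnatomicalVolume: ...


def validate_semantic_mask(mask: AnatomicalVolume, image: AnatomicalVolume | None = None) -> None:
    """Reject masks with unknown codes or a grid not congruent with the image."""
    if image is not None and not mask.same_grid(image):
        raise BackendContractError(
            f"semantic mask grid {mask.shape} not congruent with image grid {image.shape}"
        )
    values = np.unique(mask.data)
    allowed = SCHEME.all_codes | {BACKGROUND}
    unknown = set(int(v) for v in values) - allowed
    if unknown:
        raise BackendContractError(f"semantic mask contains unknown codes {sorted(unknown)}")


def segment_semantic(image: AnatomicalVolume, backend: SemanticBackend) -> AnatomicalVolume:
    """Run phase 1 and validate the result before it reaches phase 2."""
    mask = backend(image)
    if not isinstance(mask, AnatomicalVolume):
        raise BackendContractError("backend must return an AnatomicalVolume")
    validate_semantic_mask(mask, image)
    return mask


class OracleSemanticBackend:
    """Returns the phantom's ground-truth semantic mask (a perfect model)."""

    def __init__(self, truth: AnatomicalVolume):
        self.truth = truth

    def __call__(self, image: AnatomicalVolume) -> AnatomicalVolume:
        if image.shape != self.truth.shape:
            raise BackendContractError("image grid does not match the oracle's truth grid")
        return self.truth


class NoisySemanticBackend:
    """Oracle plus a deterministic corruption emulating model errors."""

    def __init__(self, truth: AnatomicalVolume, noise: CorruptionSpec | Mapping, seed: int):
        self.truth = truth
        self.noise = noise
        self.seed = seed

    def __call__(self, image: AnatomicalVolume) -> AnatomicalVolume:
        if image.shape != self.truth.shape:
            raise BackendContractError("image grid does not match the oracle's truth grid")
        return corrupt_mask(self.truth, self.noise, self.seed)


def load_external_backend(name: str) -> SemanticBackend:
    """Load a backend factory from the ``spineseg.backends`` entry-point group.

    Adapter point for trained networks: the entry point must resolve to a
    zero-argument callable returning a :class:`SemanticBackend`.
    """
    eps = entry_points(group="spineseg.backends")
    for ep in eps:
        if ep.name == name:
            factory: Callable[[], SemanticBackend] = ep.load()
            return factory()
    raise LookupError(f"no semantic backend registered under entry point {name!r}")
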
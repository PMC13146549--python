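"""Pluggable per-residue contextual embedding backends.

The default ``stub`` backend produces deterministic pseudo-embeddings at any
requested width: each residue's row is drawn from a PRNG seeded by a hash of
(seed, absolute position, local sequence window), so rows are contextual
(the same letter embeds differently in different windows), reproducible, and
approximately zero-mean / unit-variance per dimension.  It lets the whole
pipeline run at desk scale with no model download.

A real ESM-2 adapter can be registered under ``esm2-t33`` when the optional
``fair-esm``/``torch`` stack is importable; the core package never requires
it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np


@dataclass
class EmbeddingBackend:
    name: str
    width: int = 1280
    supports_finetune: bool = False

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class StubBackend(EmbeddingBackend):
    """Deterministic hash-based embeddings; no learned content.

    ``context`` is the window radius: residues farther than ``context``
    positions away never influence a row.
    """

    def __init__(self, width: int = 1280, seed: int = 0, context: int = 2):
        super().__init__(name="stub", width=width, supports_finetune=False)
        if width < 1:
            raise ValueError("width must be >= 1")
        self.seed = seed
        self.context = context
        self._cache: dict[str, np.ndarray] = {}

    def _row_seed(self, window: str, position: int) -> int:
        key = f"{self.seed}|{position}|{window}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        return int.from_bytes(digest, "little") % (2**63)

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("empty sequence")
        cached = self._cache.get(sequence)
        if cached is not None:
            return cached
        c = self.context
        rows = np.empty((len(sequence), self.width))
        for i in range(len(sequence)):
            window = sequence[max(0, i - c) : i + c + 1]
            rng = np.random.Generator(np.random.PCG64(self._row_seed(window, i)))
            rows[i] = rng.standard_normal(self.width)
        self._cache[sequence] = rows
        return rows


_REGISTRY: dict[str, Callable[..., EmbeddingBackend]] = {}


def register_backend(name: str, factory: Callable[..., EmbeddingBackend]) -> None:
    if name in _REGISTRY:
        raise KeyError(f"backend {name!r} already registered")
    _REGISTRY[name] = factory


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}") from None
    return factory(**kwargs)


def list_backends() -> list[str]:
    return sorted(_REGISTRY)


register_backend("stub", StubBackend)


def _make_esm2(width: int = 1280, **kwargs) -> EmbeddingBackend:  # pragma: no cover
    """Adapter for the 33-layer ESM-2 model (final-layer hidden states).

    Requires the optional torch + fair-esm stack; long sequences are
    truncated at the model context limit with a warning.
    """
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:
        raise RuntimeError(
            "the esm2-t33 backend needs the optional 'fair-esm' and 'torch' packages"
        ) from exc

    class Esm2Backend(EmbeddingBackend):
        def __init__(self):
            super().__init__(name="esm2-t33", width=1280, supports_finetune=True)
            self.model, self.alphabet = esm.pretrained.esm2_t33_650M_UR50D()
            self.model.eval()
            self.batch_converter = self.alphabet.get_batch_converter()

        def embed(self, sequence: str) -> np.ndarray:
            import warnings

            limit = 1022
            if len(sequence) > limit:
                warnings.warn(f"truncating sequence of length {len(sequence)} to {limit}")
                sequence = sequence[:limit]
            _, _, tokens = self.batch_converter([("q", sequence)])
            with torch.no_grad():
                out = self.model(tokens, repr_layers=[33])
            rep = out["representations"][33][0, 1 : len(sequence) + 1]
            return rep.numpy().astype(np.float64)

    return Esm2Backend()


try:  # registered only when the optional stack is importable
    import esm  # type: ignore # noqa: F401

    register_backend("esm2-t33", _make_esm2)
except ImportError:
    pass


def embed_sequence(sequence: str, backend: EmbeddingBackend) -> np.ndarray:
    """One embedding row per residue, shape (L, backend.width)."""
    return backend.embed(sequence)


class EmbeddingCache:
    """Optional on-disk HDF5 cache keyed by (backend name, sequence hash)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    @staticmethod
    def _key(backend: EmbeddingBackend, sequence: str) -> str:
        h = hashlib.sha256(sequence.encode()).hexdigest()[:32]
        return f"{backend.name}/w{backend.width}/{h}"

    def embed(self, sequence: str, backend: EmbeddingBackend) -> np.ndarray:
        import h5py

        key = self._key(backend, sequence)
        with h5py.File(self.path, "a") as fh:
            if key in fh:
                return fh[key][()]
            block = backend.embed(sequence)
            fh.create_dataset(key, data=block)
            return block
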
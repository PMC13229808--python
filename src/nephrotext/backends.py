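"""Frozen causal language-model embedding backends.

The pipeline treats a language model purely as a fixed feature extractor:
the narrative is tokenized, a forward pass produces per-layer hidden states,
and the state at the final (last non-padding) token of each of the last K
layers summarizes the sequence, since in a decoder-only model only the last
token attends to the whole context.  No gradient ever flows into a backend.

Two implementations share the interface: a deterministic mock backend whose
"hidden states" are seeded hashes of (token, layer, position) — reproducible
across processes, no checkpoints, the workhorse for tests — and an optional
adapter for HuggingFace causal-LM checkpoints that is only importable when
torch/transformers are installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .serialize import Narrative

__all__ = [
    "BackendSpec",
    "LayerStack",
    "MockBackend",
    "TransformersBackend",
    "make_mock_backend",
    "extract_layer_stack",
    "mean_pooled_primary",
]

DEFAULT_K_LAYERS = 5


@dataclass(frozen=True)
class BackendSpec:
    """Geometry and role of one embedding backend."""

    name: str
    hidden_dim: int
    num_layers: int
    role: str = "primary"     # "primary" | "secondary"

    def __post_init__(self):
        if self.hidden_dim < 1 or self.num_layers < 1:
            raise ConfigError("backend hidden_dim and num_layers must be >= 1")
        if self.role not in ("primary", "secondary"):
            raise ConfigError(f"backend role must be primary/secondary, got {self.role!r}")


@dataclass(frozen=True)
class LayerStack:
    """K x D matrix of last-token hidden states, one row per layer (ascending)."""

    backend: str
    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ConfigError("layer stack must be a 2-D matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ConfigError("layer stack contains non-finite entries")


class MockBackend:
    """Deterministic stand-in for a frozen causal LM (synthetic states).

    Token states are standard-normal vectors derived from a BLAKE2 hash of
    (seed, layer, position, token), so any change to the narrative text
    changes the extracted features, while repeated extraction is bit-exact
    and independent of process state.
    """

    def __init__(self, name: str, hidden_dim: int, num_layers: int, seed: int,
                 role: str = "primary"):
        self.spec = BackendSpec(name=name, hidden_dim=hidden_dim,
                                num_layers=num_layers, role=role)
        self.seed = int(seed)

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        tokens = text.split()
        if not tokens:
            raise ValueError("cannot embed empty text")
        return tokens

    def _token_state(self, token: str, layer: int, position: int) -> np.ndarray:
        key = f"{self.seed}|{layer}|{position}|{token}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
        return rng.standard_normal(self.spec.hidden_dim)

    def layer_stack(self, text: str, k_layers: int = DEFAULT_K_LAYERS) -> np.ndarray:
        """(K, D) last-token states of layers L-K+1 .. L (embedding layer excluded)."""
        L = self.spec.num_layers
        if k_layers > L:
            raise ConfigError(f"requested last {k_layers} layers but backend has only {L}")
        tokens = self._tokenize(text)
        last = len(tokens) - 1
        rows = [self._token_state(tokens[last], layer, last)
                for layer in range(L - k_layers + 1, L + 1)]
        return np.stack(rows)

    def mean_pooled(self, text: str) -> np.ndarray:
        """Token-mean of the final layer's hidden states."""
        tokens = self._tokenize(text)
        L = self.spec.num_layers
        states = [self._token_state(tok, L, pos) for pos, tok in enumerate(tokens)]
        return np.mean(states, axis=0)


class TransformersBackend:
    """Adapter for a HuggingFace causal-LM checkpoint (optional runtime plugin).

    Requires torch and transformers; the model is loaded in eval mode with
    gradients disabled and is never updated.  Last token = last non-padding
    position under right padding, or the final sequence position under left
    padding.
    """

    def __init__(self, name: str, checkpoint: str, role: str = "primary",
                 device: str = "cpu"):
        try:
            import torch
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "TransformersBackend requires the optional 'llm' extra "
                "(torch + transformers); use MockBackend for checkpoint-free runs"
            ) from exc
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(checkpoint)
        self._model = AutoModel.from_pretrained(checkpoint, output_hidden_states=True)
        self._model.eval().to(device)
        for p in self._model.parameters():
            p.requires_grad_(False)
        self._device = device
        cfg = self._model.config
        self.spec = BackendSpec(name=name, hidden_dim=cfg.hidden_size,
                                num_layers=cfg.num_hidden_layers, role=role)

    def _hidden_states(self, text: str):  # pragma: no cover - needs checkpoint
        if not text.strip():
            raise ValueError("cannot embed empty text")
        enc = self._tokenizer(text, return_tensors="pt").to(self._device)
        with self._torch.no_grad():
            out = self._model(**enc)
        # out.hidden_states: (L+1) tensors incl. embedding output; drop index 0
        return [h[0].cpu().numpy() for h in out.hidden_states[1:]]

    def layer_stack(self, text: str, k_layers: int = DEFAULT_K_LAYERS) -> np.ndarray:  # pragma: no cover
        L = self.spec.num_layers
        if k_layers > L:
            raise ConfigError(f"requested last {k_layers} layers but backend has only {L}")
        layers = self._hidden_states(text)
        return np.stack([layers[i][-1] for i in range(L - k_layers, L)])

    def mean_pooled(self, text: str) -> np.ndarray:  # pragma: no cover
        return self._hidden_states(text)[-1].mean(axis=0)


def make_mock_backend(name: str, hidden_dim: int, num_layers: int, seed: int,
                      role: str = "primary") -> MockBackend:
    """Construct a deterministic mock backend (see :class:`MockBackend`)."""
    return MockBackend(name, hidden_dim, num_layers, seed, role=role)


def extract_layer_stack(narrative: Narrative, backend,
                        k_layers: int = DEFAULT_K_LAYERS) -> LayerStack:
    """Last-token states of the backend's last ``k_layers`` layers, as a LayerStack."""
    matrix = backend.layer_stack(narrative.text, k_layers=k_layers)
    return LayerStack(backend=backend.spec.name, matrix=matrix)


def mean_pooled_primary(narrative: Narrative, backend) -> np.ndarray:
    """Token-mean final-layer embedding of the primary backend (tail of the fused vector)."""
    if backend.spec.role != "primary":
        raise ConfigError("mean-pooled embedding is defined for the primary backend only")
    return backend.mean_pooled(narrative.text)
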
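"""Adapter for a pre-trained protein language model (optional plug-in).

Satisfies the same contract as the mock embedder: deterministic in eval
mode, fixed output dimension, pooling applied over the final hidden states.
Requires ``torch`` and ``transformers``, which are deliberately not package
dependencies; importing this module without them raises ``ImportError``.
"""

from __future__ import annotations

import numpy as np

from .embedding import EmbedderSpec, _pool, _validate_sequence

_DEFAULT_MODEL = "Rostlab/prot_t5_xl_half_uniref50-enc"


class ProtT5Embedder:
    """Pool per-residue final hidden states of a ProtT5-style encoder."""

    def __init__(self, spec: EmbedderSpec, model_name: str = _DEFAULT_MODEL) -> None:
        try:
            import torch
            from transformers import T5EncoderModel, T5Tokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the 'plm' embedder requires torch and transformers; "
                "install them or use the 'mock' embedder"
            ) from exc
        self.spec = spec
        self._torch = torch
        self._tokenizer = T5Tokenizer.from_pretrained(model_name, legacy=True)
        self._model = T5EncoderModel.from_pretrained(model_name).eval()

    def __call__(self, sequence: str) -> np.ndarray:  # pragma: no cover
        _validate_sequence(sequence)
        spaced = " ".join(sequence)
        tokens = self._tokenizer(spaced, return_tensors="pt")
        with self._torch.no_grad():
            hidden = self._model(**tokens).last_hidden_state[0]
        # Drop the trailing special token so rows align with residues.
        residue_states = hidden[: len(sequence)].cpu().numpy().astype(np.float64)
        return _pool(residue_states, self.spec.pooling)
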
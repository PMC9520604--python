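"""Discrete entropy and stimulus-response mutual information.

Responses (mean population counts over the readout window) are discretised
into equal-width bins, and plug-in (maximum-likelihood) entropies are
computed in bits: MI(S;R) = H(R) - H(R|S).  H(R) alone is the information
capacity; the conditional term penalises unreliable responses, which is
what separates the two quantities near a phase transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusResponseTable", "InfoResult", "bin_responses", "entropies"]


@dataclass
class StimulusResponseTable:
    stimuli: np.ndarray          # trial-wise stimulus level labels
    responses: np.ndarray        # trial-wise scalar responses

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.stimuli) != len(self.responses):
            raise ValueError("stimuli and responses must have equal length")
        if len(self.stimuli) == 0:
            raise ValueError("empty stimulus-response table")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses must be finite")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.stimuli))


@dataclass
class InfoResult:
    H_R: float                   # bits
    H_R_given_S: float           # bits
    MI: float                    # bits
    bin_edges: np.ndarray | None = None


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def bin_responses(responses, n_bins: int = 8,
                  edges: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width discretisation of scalar responses.

    Returns integer symbols in ``0..n_bins-1`` and the bin edges used.
    Constant responses map to a single symbol (zero response entropy, not an
    error).  Pass precomputed ``edges`` to bin two conditions on a common
    scale.
    """
    r = np.asarray(responses, dtype=float)
    if edges is None:
        lo, hi = float(r.min()), float(r.max())
        if lo == hi:
            return np.zeros(len(r), dtype=np.int64), np.array([lo, hi])
        edges = np.linspace(lo, hi, n_bins + 1)
    symbols = np.clip(np.digitize(r, edges[1:-1], right=False), 0,
                      len(edges) - 2)
    return symbols.astype(np.int64), np.asarray(edges)


def entropies(table: StimulusResponseTable, n_bins: int = 8,
              edges: np.ndarray | None = None) -> InfoResult:
    """Plug-in entropies of the binned responses.

    H(R|S) is the stimulus-weighted average of the per-stimulus response
    entropies; MI follows by subtraction.  No bias correction is applied,
    so at small trial counts MI carries the usual positive plug-in bias.
    """
    symbols, used_edges = bin_responses(table.responses, n_bins=n_bins,
                                        edges=edges)
    H_R = _entropy_bits(symbols)
    levels, inv = np.unique(table.stimuli, return_inverse=True)
    H_cond = 0.0
    for i in range(len(levels)):
        sel = inv == i
        H_cond += sel.mean() * _entropy_bits(symbols[sel])
    return InfoResult(H_R=H_R, H_R_given_S=float(H_cond),
                      MI=float(H_R - H_cond), bin_edges=used_edges)
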
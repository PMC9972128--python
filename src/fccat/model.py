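"""Thurstonian IRT pairwise response model.

A forced-choice pair presents two items *i* and *k* from different scales and
asks which describes the respondent better.  Under the Thurstonian IRT model
each item has a normally distributed latent utility; the first item is
preferred (``Y = 1``) when its utility exceeds the second's, which gives the
probit item response function

.. math::

    P(Y_{\\{i,k\\}} = 1 \\mid \\eta)
      = \\Phi\\!\\left(\\frac{\\mu_i - \\mu_k + (\\lambda_i - \\lambda_k)^T \\eta}
                           {\\sqrt{\\psi_i^2 + \\psi_k^2}}\\right)
      \\equiv \\Phi(z_{\\{i,k\\}}),

where :math:`\\eta` is the S-vector of latent trait scores.  With factorially
simple items the loading difference has at most two nonzero entries, so a pair
informs only the two traits it crosses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

from .bank import ItemBank

__all__ = [
    "PairBlock",
    "ResponseRecord",
    "pair_z",
    "pair_probability",
    "simulate_response",
    "simulate_session",
    "Z_CLAMP",
]

#: |z| is clamped here before evaluating the normal CDF, keeping probabilities
#: strictly inside (0, 1) for downstream likelihood and information formulas.
Z_CLAMP = 8.0


@dataclass(frozen=True)
class PairBlock:
    """A forced-choice pair: ``first`` is the item coded Y=1 when preferred."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("a pair must contain two distinct items")

    def reversed(self) -> "PairBlock":
        return PairBlock(self.second, self.first)


@dataclass(frozen=True)
class ResponseRecord:
    """A pair together with the observed binary preference."""

    block: PairBlock
    y: int

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"y must be 0 or 1, got {self.y!r}")


def _as_eta(eta, n_scales: int) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (n_scales,):
        raise ValueError(f"eta must have shape ({n_scales},), got {eta.shape}")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return eta


def _pair_indices(block: PairBlock, bank: ItemBank) -> tuple[int, int]:
    return bank.index(block.first), bank.index(block.second)


def pair_z(block: PairBlock, eta, bank: ItemBank) -> float:
    """The probit argument ``z`` for preferring ``block.first`` at trait profile ``eta``."""
    i, k = _pair_indices(block, bank)
    eta = _as_eta(eta, bank.n_scales)
    num = bank.mu[i] - bank.mu[k] + bank.loading[i] * eta[bank.scale_idx[i]] - bank.loading[k] * eta[bank.scale_idx[k]]
    return float(num / np.sqrt(bank.psi2[i] + bank.psi2[k]))


def pair_probability(block: PairBlock, eta, bank: ItemBank) -> float:
    """P(first preferred | eta) = Phi(z), with z clamped to +-``Z_CLAMP``."""
    z = pair_z(block, eta, bank)
    return float(ndtr(np.clip(z, -Z_CLAMP, Z_CLAMP)))


def simulate_response(block: PairBlock, eta, bank: ItemBank, rng: np.random.Generator) -> ResponseRecord:
    """Draw ``y ~ Bernoulli(pair_probability)``; consumes one uniform variate."""
    p = pair_probability(block, eta, bank)
    return ResponseRecord(block, int(rng.random() < p))


def simulate_session(
    form: Sequence[PairBlock], eta, bank: ItemBank, rng: np.random.Generator
) -> list[ResponseRecord]:
    """Simulate responses to an ordered form, one record per block, order preserved."""
    return [simulate_response(b, eta, bank, rng) for b in form]


def records_to_jsonl(records: Iterable[ResponseRecord]) -> str:
    """Serialize a response stream as JSON lines ``{step, first, second, y}``."""
    import json

    lines = [
        json.dumps({"step": t + 1, "first": r.block.first, "second": r.block.second, "y": r.y})
        for t, r in enumerate(records)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def records_from_jsonl(text: str) -> list[ResponseRecord]:
    """Parse a JSON-lines response stream written by :func:`records_to_jsonl`."""
    import json

    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        out.append(ResponseRecord(PairBlock(obj["first"], obj["second"]), int(obj["y"])))
    return out
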
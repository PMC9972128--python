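"""Calibrated forced-choice item banks: containers, CSV I/O, validation, synthesis.

An item bank holds factorially simple "dominance" items (here: personality
adjectives).  Each item *i* carries the parameters of its latent utility in the
Thurstonian IRT parameterization obtained from single-stimulus calibration:

* ``mu`` — the mean utility :math:`\\mu_i` on the calibration response scale,
* ``loading`` — the single nonzero factor loading :math:`\\lambda_{i,s_i}` on the
  item's own trait (its sign encodes positive/negative keying),
* ``uniqueness`` — the residual utility variance :math:`\\psi_i^2 > 0`.

The conventional IRT-style discrimination of an item is
:math:`|\\lambda_{i,s_i}/\\psi_i|`.

Because the real adjective bank is proprietary, :func:`synthesize_bank` generates
banks that emulate its printed composition: 279 items over the six HEXACO scales
(Honesty-Humility, Emotionality, eXtraversion, Agreeableness, Conscientiousness,
Openness), per-scale discrimination summaries, and the bank-level utility
distribution (mean 3.61, SD 1.54, range [1.22, 5.80]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Item",
    "ItemBank",
    "BankSummary",
    "BankRecipe",
    "BankFormatError",
    "BankValidationError",
    "RecipeError",
    "load_bank",
    "write_bank",
    "summarize_bank",
    "synthesize_bank",
    "DEFAULT_SCALES",
]

#: HEXACO scale labels in their declared order; indices 0..5 follow this order.
DEFAULT_SCALES: tuple[str, ...] = ("H", "E", "X", "A", "C", "O")

BANK_COLUMNS: tuple[str, ...] = ("item_id", "scale", "mu", "loading", "uniqueness")

#: Per-scale (mean, min, max) targets for |lambda/psi| of the default synthetic bank.
DEFAULT_DISCRIMINATION_TARGETS: Mapping[str, tuple[float, float, float]] = {
    "H": (0.49, 0.15, 0.78),
    "E": (0.52, 0.17, 0.97),
    "X": (0.68, 0.20, 1.18),
    "A": (0.61, 0.20, 1.01),
    "C": (0.61, 0.22, 1.18),
    "O": (0.49, 0.20, 1.03),
}

#: Default per-scale item counts (sum 279, each within the printed 24-81 span).
DEFAULT_SCALE_COUNTS: Mapping[str, int] = {
    "H": 40,
    "E": 45,
    "X": 50,
    "A": 46,
    "C": 52,
    "O": 46,
}


class BankFormatError(ValueError):
    """A bank file/table does not have the expected columns or dialect."""


class BankValidationError(ValueError):
    """Bank contents violate an item or bank invariant."""


class RecipeError(ValueError):
    """A synthetic-bank recipe is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class Item:
    """One forced-choice dominance item with its calibrated utility parameters."""

    item_id: str
    scale: str
    mu: float
    loading: float
    uniqueness: float

    def __post_init__(self) -> None:
        if not self.item_id:
            raise BankValidationError("item_id must be a non-empty string")
        if not math.isfinite(self.mu):
            raise BankValidationError(f"item {self.item_id!r}: mu must be finite")
        if not math.isfinite(self.loading) or self.loading == 0.0:
            raise BankValidationError(
                f"item {self.item_id!r}: loading must be finite and nonzero "
                "(each item loads on exactly one trait)"
            )
        if not math.isfinite(self.uniqueness) or self.uniqueness <= 0.0:
            raise BankValidationError(
                f"item {self.item_id!r}: uniqueness must be > 0, got {self.uniqueness}"
            )

    @property
    def keyed(self) -> int:
        """+1 for positively keyed items, -1 for negatively keyed (sign of loading)."""
        return 1 if self.loading > 0 else -1

    @property
    def discrimination(self) -> float:
        """|lambda / psi|, the IRT-style discrimination of the item."""
        return abs(self.loading) / math.sqrt(self.uniqueness)


class ItemBank:
    """An ordered collection of items spanning ``n_scales`` latent traits.

    Parameters
    ----------
    items
        Items in bank order.
    scales
        Scale labels in declared order.  If omitted, the default HEXACO order
        is used when every item scale belongs to it, otherwise labels are taken
        in order of first appearance.
    """

    def __init__(self, items: Iterable[Item], scales: Sequence[str] | None = None):
        items = tuple(items)
        if not items:
            raise BankValidationError("an item bank must contain at least one item")
        seen_scales: list[str] = []
        for it in items:
            if it.scale not in seen_scales:
                seen_scales.append(it.scale)
        if scales is None:
            if set(seen_scales) <= set(DEFAULT_SCALES):
                scales = tuple(s for s in DEFAULT_SCALES if s in seen_scales)
            else:
                scales = tuple(seen_scales)
        else:
            scales = tuple(scales)
            missing = set(seen_scales) - set(scales)
            if missing:
                raise BankValidationError(f"items reference undeclared scales: {sorted(missing)}")
        for s in scales:
            if s not in seen_scales:
                raise BankValidationError(f"scale {s!r} has no items")

        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankValidationError(f"duplicate item ids: {dupes}")

        self._items = items
        self._scales = scales
        self._index = {it.item_id: j for j, it in enumerate(items)}
        self._scale_index = {s: j for j, s in enumerate(scales)}
        # Parameter arrays in bank order, used throughout the numeric engine.
        self.mu = np.array([it.mu for it in items], dtype=float)
        self.loading = np.array([it.loading for it in items], dtype=float)
        self.psi2 = np.array([it.uniqueness for it in items], dtype=float)
        self.scale_idx = np.array([self._scale_index[it.scale] for it in items], dtype=np.intp)
        self.mu.setflags(write=False)
        self.loading.setflags(write=False)
        self.psi2.setflags(write=False)
        self.scale_idx.setflags(write=False)
        self._pool_cache: dict = {}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> Item:
        try:
            return self._items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, ItemBank):
            return NotImplemented
        return self._items == other._items and self._scales == other._scales

    def __repr__(self) -> str:
        return f"<ItemBank: {len(self)} items, {self.n_scales} scales {self._scales}>"

    # -- accessors ----------------------------------------------------------
    @property
    def items(self) -> tuple[Item, ...]:
        return self._items

    @property
    def scales(self) -> tuple[str, ...]:
        return self._scales

    @property
    def n_scales(self) -> int:
        return len(self._scales)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self._items)

    def index(self, item_id: str) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def scale_of(self, item_id: str) -> str:
        return self._items[self.index(item_id)].scale

    def items_on_scale(self, scale: str) -> tuple[Item, ...]:
        return tuple(it for it in self._items if it.scale == scale)

    @property
    def discrimination(self) -> np.ndarray:
        return np.abs(self.loading) / np.sqrt(self.psi2)

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": list(self.item_ids),
                "scale": [it.scale for it in self._items],
                "mu": self.mu,
                "loading": self.loading,
                "uniqueness": self.psi2,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scales: Sequence[str] | None = None) -> "ItemBank":
        missing = [c for c in BANK_COLUMNS if c not in frame.columns]
        if missing:
            raise BankFormatError(f"missing required columns: {missing}")
        items = []
        for row_no, row in enumerate(frame.itertuples(index=False)):
            try:
                items.append(
                    Item(
                        item_id=str(row.item_id),
                        scale=str(row.scale),
                        mu=float(row.mu),
                        loading=float(row.loading),
                        uniqueness=float(row.uniqueness),
                    )
                )
            except BankValidationError as exc:
                raise BankValidationError(f"row {row_no}: {exc}") from None
        return cls(items, scales=scales)

    def to_csv(self, path) -> None:
        # Shortest round-trip float representation keeps write->read lossless.
        self.to_frame().to_csv(path, index=False, float_format=lambda v: repr(float(v)))

    @classmethod
    def from_csv(cls, path, scales: Sequence[str] | None = None) -> "ItemBank":
        try:
            frame = pd.read_csv(
                path, dtype={"item_id": str, "scale": str}, float_precision="round_trip"
            )
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise BankFormatError(f"cannot parse bank file {path}: {exc}") from None
        return cls.from_frame(frame, scales=scales)


def load_bank(path, scales: Sequence[str] | None = None) -> ItemBank:
    """Read and validate a bank from CSV (columns ``item_id,scale,mu,loading,uniqueness``)."""
    return ItemBank.from_csv(path, scales=scales)


def write_bank(bank: ItemBank, path) -> None:
    """Write a bank to CSV in canonical formatting (round-trips losslessly)."""
    bank.to_csv(path)


@dataclass(frozen=True)
class BankSummary:
    """Per-scale composition summary: discrimination and utility statistics."""

    frame: pd.DataFrame  # indexed by scale label

    def __post_init__(self) -> None:
        f = self.frame
        if not ((f["disc_min"] <= f["disc_mean"] + 1e-12) & (f["disc_mean"] <= f["disc_max"] + 1e-12)).all():
            raise BankValidationError("summary violates min <= mean <= max")

    def to_csv(self, path) -> None:
        """Write the per-scale |lambda/psi| summary (columns scale, mean, min, max)."""
        out = self.frame[["disc_mean", "disc_min", "disc_max"]].copy()
        out.columns = ["mean", "min", "max"]
        out.index.name = "scale"
        out.to_csv(path, float_format="%.6g")

    @property
    def utility_mean(self) -> float:
        f = self.frame
        return float((f["mu_sum"]).sum() / f["n_items"].sum())

    def __repr__(self) -> str:
        return f"BankSummary(\n{self.frame}\n)"


def summarize_bank(bank: ItemBank) -> BankSummary:
    """Per-scale statistics of |lambda/psi| and of the mean utilities."""
    disc = bank.discrimination
    rows = {}
    for s in bank.scales:
        m = bank.scale_idx == bank._scale_index[s]
        d = disc[m]
        u = bank.mu[m]
        rows[s] = {
            "n_items": int(m.sum()),
            "disc_mean": float(d.mean()),
            "disc_min": float(d.min()),
            "disc_max": float(d.max()),
            "mu_mean": float(u.mean()),
            "mu_sd": float(u.std(ddof=1)) if m.sum() > 1 else 0.0,
            "mu_min": float(u.min()),
            "mu_max": float(u.max()),
            "mu_sum": float(u.sum()),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[list(bank.scales)]
    frame.index.name = "scale"
    return BankSummary(frame)


@dataclass(frozen=True)
class BankRecipe:
    """Recipe for a synthetic bank emulating the printed adjective-bank composition.

    Utilities are drawn from a keying-linked mixture of truncated normals:
    negatively keyed (undesirable) items from the low component, positively
    keyed (desirable) items from the high component.  A single truncated normal
    cannot simultaneously have SD ~1.5 and support on [1.22, 5.80]; the printed
    utility summary implies a bimodal desirable/undesirable mixture.

    Discriminations |lambda/psi| per scale are drawn from a Beta distribution
    rescaled to the target [min, max], with its mean matched (and the sample
    mean re-centred) to the target mean.  Loadings are standardized so that
    lambda^2 + psi^2 = 1 (unit-variance traits and utilities), i.e.
    ``lambda = d / sqrt(1 + d^2)`` for discrimination ``d``.
    """

    scales: tuple[str, ...] = DEFAULT_SCALES
    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SCALE_COUNTS))
    discrimination_targets: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DISCRIMINATION_TARGETS)
    )
    discrimination_concentration: float = 4.0
    discrimination_tolerance: float = 0.05
    negative_fraction: float = 0.42
    utility_bounds: tuple[float, float] = (1.22, 5.80)
    utility_locations: tuple[float, float] = (1.70, 4.95)  # (negative-keyed, positive-keyed)
    utility_scale: float = 0.60

    def validate(self) -> None:
        if not self.scales:
            raise RecipeError("at least one scale is required")
        for s in self.scales:
            if s not in self.counts:
                raise RecipeError(f"no item count for scale {s!r}")
            if self.counts[s] < 1:
                raise RecipeError(f"scale {s!r}: count must be >= 1")
            if s not in self.discrimination_targets:
                raise RecipeError(f"no discrimination target for scale {s!r}")
            mean, lo, hi = self.discrimination_targets[s]
            if not (0 < lo <= mean <= hi) or lo == hi and self.counts[s] > 1:
                raise RecipeError(
                    f"scale {s!r}: discrimination targets must satisfy 0 < min <= mean <= max"
                )
            if lo > hi:
                raise RecipeError(f"scale {s!r}: discrimination min > max")
        lo, hi = self.utility_bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise RecipeError("utility bounds must be finite with min < max")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise RecipeError("negative_fraction must lie in [0, 1]")
        if self.discrimination_concentration <= 0:
            raise RecipeError("discrimination_concentration must be > 0")
        if self.utility_scale <= 0:
            raise RecipeError("utility_scale must be > 0")
        for loc in self.utility_locations:
            if not math.isfinite(loc):
                raise RecipeError("utility locations must be finite")


def _truncnorm_rvs(loc: float, scale: float, lo: float, hi: float, size: int, rng) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def synthesize_bank(recipe: BankRecipe | None = None, seed: int = 0) -> ItemBank:
    """Generate a validated synthetic bank; deterministic given ``seed``.

    With the default recipe the bank has 279 items across the six HEXACO
    scales, per-scale |lambda/psi| summaries near the printed calibration
    summaries, and utilities with mean ~3.61, SD ~1.54 on [1.22, 5.80].
    """
    recipe = recipe or BankRecipe()
    recipe.validate()
    rng = np.random.default_rng(seed)
    lo, hi = recipe.utility_bounds
    items: list[Item] = []
    for s in recipe.scales:
        n = int(recipe.counts[s])
        mean_t, min_t, max_t = recipe.discrimination_targets[s]
        if max_t > min_t:
            m = (mean_t - min_t) / (max_t - min_t)
            m = min(max(m, 1e-6), 1 - 1e-6)
            kappa = recipe.discrimination_concentration
            d = min_t + (max_t - min_t) * rng.beta(m * kappa, (1 - m) * kappa, size=n)
            # Re-centre the sample mean onto the target (clip keeps the range).
            for _ in range(3):
                d = np.clip(d + (mean_t - d.mean()), min_t, max_t)
        else:
            d = np.full(n, mean_t)
        lam = d / np.sqrt(1.0 + d**2)
        psi2 = 1.0 - lam**2

        n_neg = int(round(recipe.negative_fraction * n))
        keyed = np.ones(n)
        keyed[:n_neg] = -1.0
        keyed = keyed[rng.permutation(n)]
        mu = np.empty(n)
        neg = keyed < 0
        loc_neg, loc_pos = recipe.utility_locations
        mu[neg] = _truncnorm_rvs(loc_neg, recipe.utility_scale, lo, hi, int(neg.sum()), rng)
        mu[~neg] = _truncnorm_rvs(loc_pos, recipe.utility_scale, lo, hi, int((~neg).sum()), rng)

        for j in range(n):
            items.append(
                Item(
                    item_id=f"{s}{j + 1:03d}",
                    scale=s,
                    mu=float(mu[j]),
                    loading=float(keyed[j] * lam[j]),
                    uniqueness=float(psi2[j]),
                )
            )
    return ItemBank(items, scales=recipe.scales)
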
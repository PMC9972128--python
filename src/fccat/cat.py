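"""Adaptive pair selection, session control, and static-optimal test assembly.

The selection rule is Bayesian A-optimality under a social-desirability
balancing constraint.  At each step:

(a) all cross-scale pairs of not-yet-administered items are enumerated,
(b) pairs whose mean-utility difference exceeds the desirability threshold
    ``T`` are removed (mean utility is the desirability proxy),
(c) among the remaining candidates the pair minimizing
    ``trace[(Sigma^-1 + I_test + F_pair(interim))^-1]`` — the total posterior
    error variance across traits — is administered.

Adaptive sessions re-estimate the interim MAP trait profile after every block
(starting from the origin); the static-optimal assembler runs the identical
greedy loop with the interim pinned at the origin, producing a fixed form
optimized for the average person in the target population.

Implementation notes: the hot loop scores all candidates at once using a
rank-one (Sherman-Morrison) update of the posterior inverse; its output is
contractually identical (to ~1e-10) to explicit matrix inversion, which the
public :func:`a_optimality_score` performs and the tests compare against.
Accumulated test information evaluates each administered pair at the interim
estimate current at administration time, so posterior information grows
monotonically over a session (and per-trait SEM trajectories never increase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .bank import ItemBank
from .estimation import MAPTraitResults, MAPTraitModel, _PairData, _fit_newton
from .information import P_CLAMP, PriorSpec, pair_information
from .model import PairBlock, ResponseRecord, Z_CLAMP

__all__ = [
    "DesirabilityConstraint",
    "SessionState",
    "TestForm",
    "SessionResult",
    "PoolExhaustedError",
    "enumerate_candidates",
    "a_optimality_score",
    "select_next_pair",
    "run_adaptive_session",
    "assemble_static_test",
    "administer_form",
]

#: Candidates whose scores agree with the minimum within this relative
#: tolerance are treated as tied and broken uniformly at random (seeded).
TIE_RTOL = 1e-12


class PoolExhaustedError(RuntimeError):
    """No eligible forced-choice pair remains under the active constraint."""


@dataclass(frozen=True)
class DesirabilityConstraint:
    """Social-desirability balancing: require ``|mu_i - mu_k| <= threshold``.

    ``threshold=None`` disables balancing.  The empirical design used 0.5
    ("strict") and 1.0 ("lenient").
    """

    threshold: float | None = 1.0

    def __post_init__(self) -> None:
        if self.threshold is not None and not (self.threshold >= 0):
            raise ValueError("desirability threshold must be nonnegative (or None)")

    @classmethod
    def from_spec(cls, spec) -> "DesirabilityConstraint":
        """Build from ``'strict' | 'lenient' | 'none'`` or a numeric threshold."""
        if isinstance(spec, DesirabilityConstraint):
            return spec
        if spec is None:
            return cls(None)
        if isinstance(spec, str):
            key = spec.strip().lower()
            named = {"strict": 0.5, "lenient": 1.0, "none": None}
            if key in named:
                return cls(named[key])
            try:
                return cls(float(key))
            except ValueError:
                raise ValueError(f"unknown desirability constraint {spec!r}") from None
        return cls(float(spec))

    @property
    def label(self) -> str:
        if self.threshold is None:
            return "none"
        if self.threshold == 0.5:
            return "strict"
        if self.threshold == 1.0:
            return "lenient"
        return f"T={self.threshold:g}"

    def allows(self, mu_diff: float) -> bool:
        return self.threshold is None or abs(mu_diff) <= self.threshold


# ---------------------------------------------------------------------------
# Candidate pool: precomputed cross-scale pair arrays, shared across sessions.
# ---------------------------------------------------------------------------


class _PairPool:
    """All cross-scale item pairs of a bank, in lexicographic id order."""

    def __init__(self, bank: ItemBank):
        ids = np.array(bank.item_ids)
        order = np.argsort(ids, kind="stable")  # lexicographic by id
        a, k = np.triu_indices(len(ids), k=1)
        a = order[a]
        k = order[k]
        cross = bank.scale_idx[a] != bank.scale_idx[k]
        self.a = a[cross]
        self.k = k[cross]
        self.mudiff = bank.mu[self.a] - bank.mu[self.k]
        self.absmu = np.abs(self.mudiff)
        psisum = bank.psi2[self.a] + bank.psi2[self.k]
        self.psisum = psisum
        self.sqrt_psisum = np.sqrt(psisum)
        self.la = bank.loading[self.a]
        self.lk = bank.loading[self.k]
        self.sa = bank.scale_idx[self.a]
        self.sk = bank.scale_idx[self.k]
        self._elig: dict = {}

    def eligible(self, constraint: DesirabilityConstraint) -> np.ndarray:
        key = constraint.threshold
        if key not in self._elig:
            if key is None:
                self._elig[key] = np.ones(self.a.size, dtype=bool)
            else:
                self._elig[key] = self.absmu <= key
        return self._elig[key]


def _pool(bank: ItemBank) -> _PairPool:
    cache = bank._pool_cache
    if "pool" not in cache:
        cache["pool"] = _PairPool(bank)
    return cache["pool"]


# ---------------------------------------------------------------------------
# Public state/record types.
# ---------------------------------------------------------------------------


@dataclass
class SessionState:
    """State of one (possibly in-progress) forced-choice session."""

    administered: list[PairBlock]
    responses: list[ResponseRecord]
    remaining: set[str]
    interim: np.ndarray
    test_info: np.ndarray
    step: int

    @classmethod
    def initial(cls, bank: ItemBank, prior: PriorSpec) -> "SessionState":
        S = bank.n_scales
        return cls(
            administered=[],
            responses=[],
            remaining=set(bank.item_ids),
            interim=prior.mean.copy(),
            test_info=np.zeros((S, S)),
            step=0,
        )

    def validate(self, bank: ItemBank) -> None:
        used = {i for b in self.administered for i in (b.first, b.second)}
        if used & self.remaining:
            raise ValueError("administered items overlap the remaining pool")
        if 2 * len(self.administered) + len(self.remaining) != len(bank):
            raise ValueError("administered/remaining partition does not cover the bank")


@dataclass(frozen=True)
class TestForm:
    """An ordered sequence of pair blocks with assembly provenance."""

    __test__ = False  # not a pytest class, despite the name

    blocks: tuple[PairBlock, ...]
    provenance: str  # "adaptive" | "static"
    constraint: DesirabilityConstraint
    seed: int | None = None
    truncated: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if b.first in seen or b.second in seen:
                raise ValueError(f"item reuse in form at pair ({b.first}, {b.second})")
            seen.update((b.first, b.second))

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    @property
    def item_ids(self) -> set[str]:
        return {i for b in self.blocks for i in (b.first, b.second)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.blocks) + 1),
                "first_item": [b.first for b in self.blocks],
                "second_item": [b.second for b in self.blocks],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, constraint=None, provenance: str = "static") -> "TestForm":
        frame = pd.read_csv(path, dtype={"first_item": str, "second_item": str})
        blocks = tuple(
            PairBlock(r.first_item, r.second_item) for r in frame.itertuples(index=False)
        )
        return cls(blocks, provenance, DesirabilityConstraint.from_spec(constraint))


@dataclass
class SessionResult:
    """Full record of one administered session.

    ``interim_trajectory[t]`` and ``sem_trajectory[t]`` are the interim MAP
    estimate and directional SEMs after block ``t+1``; SEMs come from the
    online-accumulated posterior information and are nonincreasing in ``t``.
    """

    form: TestForm
    responses: list[ResponseRecord]
    interim_trajectory: np.ndarray  # (n_blocks, S)
    sem_trajectory: np.ndarray  # (n_blocks, S)
    estimate: MAPTraitResults
    truncated: bool = False
    reason: str | None = None
    score_trajectory: np.ndarray | None = None  # (n_blocks,) A-optimality values

    def to_jsonl(self) -> str:
        """Per-step session log: ``{step, first, second, y, interim, sem, score}``."""
        import json

        lines = []
        for t, r in enumerate(self.responses):
            obj = {
                "step": t + 1,
                "first": r.block.first,
                "second": r.block.second,
                "y": r.y,
                "interim": [round(v, 10) for v in self.interim_trajectory[t]],
                "sem": [round(v, 10) for v in self.sem_trajectory[t]],
            }
            if self.score_trajectory is not None:
                obj["score"] = round(float(self.score_trajectory[t]), 10)
            lines.append(json.dumps(obj))
        return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Public, spec-shaped operations (clarity over speed; the engine is below).
# ---------------------------------------------------------------------------


def enumerate_candidates(
    state: SessionState, bank: ItemBank, constraint: DesirabilityConstraint
) -> list[PairBlock]:
    """All eligible cross-scale pairs of remaining items, lexicographic by ids."""
    if not state.remaining:
        raise PoolExhaustedError("no items remain in the pool")
    rem = sorted(state.remaining)
    out: list[PairBlock] = []
    for ii, first in enumerate(rem):
        fi = bank.index(first)
        for second in rem[ii + 1 :]:
            ki = bank.index(second)
            if bank.scale_idx[fi] == bank.scale_idx[ki]:
                continue
            if constraint.allows(bank.mu[fi] - bank.mu[ki]):
                out.append(PairBlock(first, second))
    return out


def a_optimality_score(
    candidate: PairBlock, state: SessionState, bank: ItemBank, prior: PriorSpec
) -> float:
    """Posterior A-optimality value of administering ``candidate`` next.

    ``trace[(Sigma^-1 + I_test + F_candidate(interim))^-1]`` via explicit
    inversion; lower is better.
    """
    F = pair_information(candidate, state.interim, bank)
    post = prior.cov_inv + state.test_info + F
    return float(np.trace(np.linalg.inv(post)))


def select_next_pair(
    state: SessionState,
    bank: ItemBank,
    prior: PriorSpec,
    constraint: DesirabilityConstraint,
    rng: np.random.Generator | int | None = None,
) -> PairBlock:
    """The eligible candidate with minimal A-optimality score (seeded tie-break)."""
    candidates = enumerate_candidates(state, bank, constraint)
    if not candidates:
        raise PoolExhaustedError(
            f"no eligible pair satisfies the desirability constraint ({constraint.label})"
        )
    rng = np.random.default_rng(rng)
    scores = np.array([a_optimality_score(c, state, bank, prior) for c in candidates])
    smin = scores.min()
    ties = np.flatnonzero(scores <= smin + TIE_RTOL * max(1.0, abs(smin)))
    pick = ties[0] if ties.size == 1 else rng.choice(ties)
    return candidates[int(pick)]


# ---------------------------------------------------------------------------
# Vectorized session engine.
# ---------------------------------------------------------------------------


def _score_all(pool, alive, eta, B, B2, trB):
    """A-optimality scores for candidate indices ``alive`` (rank-one update form).

    Returns (scores, c) where ``c`` is each pair's information coefficient at
    ``eta`` (F = c v v^T with sparse loading difference v).
    """
    sa = pool.sa[alive]
    sk = pool.sk[alive]
    la = pool.la[alive]
    lk = pool.lk[alive]
    z = (pool.mudiff[alive] + la * eta[sa] - lk * eta[sk]) / pool.sqrt_psisum[alive]
    np.clip(z, -Z_CLAMP, Z_CLAMP, out=z)
    p = ndtr(z)
    np.clip(p, P_CLAMP, 1.0 - P_CLAMP, out=p)
    c = np.exp(-z * z) / (2.0 * math.pi) / (p * (1.0 - p) * pool.psisum[alive])
    q1 = la * la * B[sa, sa] - 2.0 * la * lk * B[sa, sk] + lk * lk * B[sk, sk]
    q2 = la * la * B2[sa, sa] - 2.0 * la * lk * B2[sa, sk] + lk * lk * B2[sk, sk]
    scores = trB - c * q2 / (1.0 + c * q1)
    return scores, c, q1


def _pick_min(scores: np.ndarray, rng: np.random.Generator) -> int:
    smin = scores.min()
    ties = np.flatnonzero(scores <= smin + TIE_RTOL * max(1.0, abs(smin)))
    if ties.size == 1:
        return int(ties[0])
    return int(rng.choice(ties))


def _greedy_blocks(
    bank: ItemBank,
    prior: PriorSpec,
    constraint: DesirabilityConstraint,
    test_length: int,
    tie_rng: np.random.Generator,
    interim_fn: Callable[[int, int, int, float], np.ndarray],
    respond_fn=None,
):
    """Shared greedy loop for adaptive sessions and static assembly.

    ``interim_fn(step, a, k, c)`` is called after block ``step`` was
    administered (bank indices ``a, k``, information coefficient ``c``) and
    must return the interim estimate to use for the next selection.
    """
    if 2 * test_length > len(bank):
        raise ValueError(
            f"test length {test_length} needs {2 * test_length} items; bank has {len(bank)}"
        )
    pool = _pool(bank)
    elig = pool.eligible(constraint)
    S = bank.n_scales
    A = prior.cov_inv.copy()
    B = np.linalg.inv(A)
    used = np.zeros(len(bank), dtype=bool)
    eta = prior.mean.copy()
    blocks: list[tuple[int, int]] = []
    sems = np.empty((test_length, S))
    etas = np.empty((test_length, S))
    sel_scores = np.empty(test_length)
    truncated = False
    reason = None
    for step in range(test_length):
        alive = np.flatnonzero(elig & ~(used[pool.a] | used[pool.k]))
        if alive.size == 0:
            truncated = True
            reason = (
                f"pool exhausted after {step} blocks: no eligible pair remains "
                f"under constraint {constraint.label}"
            )
            sems = sems[:step]
            etas = etas[:step]
            sel_scores = sel_scores[:step]
            break
        B2 = B @ B
        trB = float(np.trace(B))
        scores, c_all, q1_all = _score_all(pool, alive, eta, B, B2, trB)
        j = _pick_min(scores, tie_rng)
        sel = alive[j]
        sel_scores[step] = scores[j]
        a, k = int(pool.a[sel]), int(pool.k[sel])
        c, q1 = float(c_all[j]), float(q1_all[j])
        # Rank-one update of A and its inverse with the selected pair's
        # information, evaluated at the current interim estimate.
        v = np.zeros(S)
        v[pool.sa[sel]] += pool.la[sel]
        v[pool.sk[sel]] -= pool.lk[sel]
        A += c * np.outer(v, v)
        Bv = B @ v
        B -= (c / (1.0 + c * q1)) * np.outer(Bv, Bv)
        if (step + 1) % 16 == 0:  # refresh against rank-one drift
            B = np.linalg.inv(A)
        used[a] = used[k] = True
        blocks.append((a, k))
        eta = interim_fn(step, a, k, c)
        etas[step] = eta
        sems[step] = np.sqrt(np.diag(B))
    return blocks, etas, sems, sel_scores, A, truncated, reason


def run_adaptive_session(
    bank: ItemBank,
    prior: PriorSpec,
    constraint: DesirabilityConstraint | str | float | None,
    test_length: int,
    true_eta=None,
    responder: Callable[[PairBlock], int] | None = None,
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SessionResult:
    """Run one adaptive session: select, administer, re-estimate, repeat.

    Responses come either from a simulee (``true_eta``, with Bernoulli noise
    drawn from ``rng``) or from a live ``responder`` callable mapping a
    :class:`PairBlock` to 0/1.  Tie-breaking and response noise use
    independent child streams of ``rng`` so that response streams stay matched
    across conditions that share a seed.
    """
    constraint = DesirabilityConstraint.from_spec(constraint)
    if (true_eta is None) == (responder is None):
        raise ValueError("provide exactly one of true_eta or responder")
    rng = np.random.default_rng(rng)
    resp_rng, tie_rng = rng.spawn(2)
    if true_eta is not None:
        true_eta = np.asarray(true_eta, dtype=float)

    ids = bank.item_ids
    S = bank.n_scales
    n_max = test_length
    ia = np.empty(n_max, dtype=np.intp)
    ik = np.empty(n_max, dtype=np.intp)
    y = np.empty(n_max)
    responses: list[ResponseRecord] = []
    fit_state = {"eta": prior.mean.copy()}

    def interim_fn(step, a, k, c):
        block = PairBlock(ids[a], ids[k])
        if responder is not None:
            yy = int(responder(block))
            if yy not in (0, 1):
                raise ValueError("responder must return 0 or 1")
        else:
            zt = (
                bank.mu[a]
                - bank.mu[k]
                + bank.loading[a] * true_eta[bank.scale_idx[a]]
                - bank.loading[k] * true_eta[bank.scale_idx[k]]
            ) / math.sqrt(bank.psi2[a] + bank.psi2[k])
            p = float(ndtr(np.clip(zt, -Z_CLAMP, Z_CLAMP)))
            yy = int(resp_rng.random() < p)
        responses.append(ResponseRecord(block, yy))
        ia[step] = a
        ik[step] = k
        y[step] = yy
        data = _PairData(ia[: step + 1], ik[: step + 1], y[: step + 1], bank)
        eta, _, _, _ = _fit_newton(data, prior, fit_state["eta"], tol, max_iter)
        fit_state["eta"] = eta
        return eta

    blocks, etas, sems, sel_scores, A, truncated, reason = _greedy_blocks(
        bank, prior, constraint, test_length, tie_rng, interim_fn
    )
    form = TestForm(
        tuple(PairBlock(ids[a], ids[k]) for a, k in blocks),
        "adaptive",
        constraint,
        truncated=truncated,
        reason=reason,
    )
    estimate = _final_estimate(responses, bank, prior, fit_state["eta"], A, tol, max_iter)
    return SessionResult(form, responses, etas, sems, estimate, truncated, reason, sel_scores)


def _final_estimate(responses, bank, prior, eta, A, tol, max_iter) -> MAPTraitResults:
    """Results object for a finished session (SEMs from accumulated information)."""
    model = MAPTraitModel(responses, bank, prior)
    grad_norm = float(np.max(np.abs(model.score(eta)))) if responses else 0.0
    sem = np.sqrt(np.diag(np.linalg.inv(A)))
    return MAPTraitResults(model, eta, sem, grad_norm <= tol, 0, grad_norm, tol)


def assemble_static_test(
    bank: ItemBank,
    prior: PriorSpec,
    constraint: DesirabilityConstraint | str | float | None,
    test_length: int,
    seed: int = 0,
) -> TestForm:
    """Greedy static-optimal assembly: the adaptive loop with interim pinned at the origin.

    Deterministic given bank, constraint and ``seed`` (used only to break
    exact score ties); the form targets the average person in the population.
    """
    constraint = DesirabilityConstraint.from_spec(constraint)
    tie_rng = np.random.default_rng(seed)
    origin = prior.mean.copy()
    blocks, _, _, _, _, truncated, reason = _greedy_blocks(
        bank, prior, constraint, test_length, tie_rng, lambda *args: origin
    )
    ids = bank.item_ids
    return TestForm(
        tuple(PairBlock(ids[a], ids[k]) for a, k in blocks),
        "static",
        constraint,
        seed=seed,
        truncated=truncated,
        reason=reason,
    )


def administer_form(
    form: TestForm,
    bank: ItemBank,
    prior: PriorSpec,
    true_eta=None,
    responder: Callable[[PairBlock], int] | None = None,
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SessionResult:
    """Administer a fixed form block by block, re-estimating after each block.

    The bookkeeping (interim MAP re-estimation, online accumulation of
    information at the interim estimate) is identical to an adaptive session,
    so static and adaptive SEM trajectories are directly comparable.
    """
    if (true_eta is None) == (responder is None):
        raise ValueError("provide exactly one of true_eta or responder")
    rng = np.random.default_rng(rng)
    resp_rng, _ = rng.spawn(2)
    if true_eta is not None:
        true_eta = np.asarray(true_eta, dtype=float)
    S = bank.n_scales
    L = len(form)
    A = prior.cov_inv.copy()
    eta = prior.mean.copy()
    ia = np.empty(L, dtype=np.intp)
    ik = np.empty(L, dtype=np.intp)
    y = np.empty(L)
    responses: list[ResponseRecord] = []
    etas = np.empty((L, S))
    sems = np.empty((L, S))
    sel_scores = np.empty(L)
    for step, block in enumerate(form):
        a, k = bank.index(block.first), bank.index(block.second)
        # Pair information at the current interim estimate.
        psisum = bank.psi2[a] + bank.psi2[k]
        z = (
            bank.mu[a]
            - bank.mu[k]
            + bank.loading[a] * eta[bank.scale_idx[a]]
            - bank.loading[k] * eta[bank.scale_idx[k]]
        ) / math.sqrt(psisum)
        z = float(np.clip(z, -Z_CLAMP, Z_CLAMP))
        p = float(np.clip(ndtr(z), P_CLAMP, 1.0 - P_CLAMP))
        c = math.exp(-z * z) / (2.0 * math.pi) / (p * (1.0 - p) * psisum)
        v = np.zeros(S)
        v[bank.scale_idx[a]] += bank.loading[a]
        v[bank.scale_idx[k]] -= bank.loading[k]
        A += c * np.outer(v, v)
        if responder is not None:
            yy = int(responder(block))
        else:
            zt = (
                bank.mu[a]
                - bank.mu[k]
                + bank.loading[a] * true_eta[bank.scale_idx[a]]
                - bank.loading[k] * true_eta[bank.scale_idx[k]]
            ) / math.sqrt(psisum)
            pt = float(ndtr(np.clip(zt, -Z_CLAMP, Z_CLAMP)))
            yy = int(resp_rng.random() < pt)
        responses.append(ResponseRecord(block, yy))
        ia[step] = a
        ik[step] = k
        y[step] = yy
        data = _PairData(ia[: step + 1], ik[: step + 1], y[: step + 1], bank)
        eta, _, _, _ = _fit_newton(data, prior, eta, tol, max_iter)
        Ainv = np.linalg.inv(A)
        etas[step] = eta
        sems[step] = np.sqrt(np.diag(Ainv))
        sel_scores[step] = np.trace(Ainv)
    estimate = _final_estimate(responses, bank, prior, eta, A, tol, max_iter)
    return SessionResult(
        form, responses, etas, sems, estimate, form.truncated, form.reason, sel_scores
    )
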
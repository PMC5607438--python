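"""Graded response model: probabilities, likelihood, information, and scoring.

The graded response model (GRM; Samejima's logistic form) describes the
probability of each ordered response category of a polytomous item as the
difference of adjacent cumulative logistic curves.  For an item with
discrimination ``a`` and ordered thresholds ``b_1 < b_2 < b_3 < b_4`` the
cumulative probability of responding in category ``k`` or higher is

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),    k = 1..4,

with the conventions ``P*_0 = 1`` and ``P*_5 = 0``, so the category
probabilities ``P_k = P*_k - P*_{k+1}`` are nonnegative and sum to one.
The slope-threshold metric is used as-is, with no ``D = 1.7`` scaling
constant: published PROMIS parameters are reported in the logistic metric,
and parameter files calibrated in another metric must be converted by the
caller.

Scoring is by maximum likelihood on the reporting scale ``[-4, 4]``: the
log-likelihood of a response pattern is maximised by Brent's method seeded
from a coarse grid, and the standard error is ``1 / sqrt(I(theta_hat))``
where ``I`` is the (expected, Fisher) test information.  All-minimum and
all-maximum patterns have no interior maximiser; they are clamped to the
scale bounds and flagged as boundary estimates with an undefined SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "THETA_BOUNDS",
    "ItemParameters",
    "ItemBank",
    "ResponsePattern",
    "ThetaEstimate",
    "cumulative_prob",
    "category_prob",
    "response_loglik",
    "item_information",
    "test_information",
    "estimate_theta",
    "FormScorer",
]

#: Reporting bounds of the latent-trait (theta) scale.
THETA_BOUNDS = (-4.0, 4.0)

N_CATEGORIES = 5  # five-point Likert response, scored 0..4
MISSING = -1  # sentinel for a missing response in integer arrays


@dataclass(frozen=True)
class ItemParameters:
    """One GRM item: a discrimination and four ordered category thresholds.

    Parameters
    ----------
    item_id
        Unique identifier of the item.
    a
        Discrimination (slope), strictly positive, logistic metric.
    b
        The four category thresholds ``b_1 < b_2 < b_3 < b_4`` in theta
        units; ``b_k`` is the theta at which responding in category ``k``
        or above has probability one half.
    label
        Optional human-readable item text.
    """

    item_id: str
    a: float
    b: tuple[float, float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"item {self.item_id!r}: discrimination must be > 0, got {self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) != N_CATEGORIES - 1:
            raise ValueError(f"item {self.item_id!r}: expected 4 thresholds, got {len(b)}")
        if not all(b[i] < b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be strictly increasing: {b}")
        object.__setattr__(self, "b", b)


class ItemBank:
    """Ordered collection of GRM items, optionally with a content pairing.

    The pairing, when present, must be a perfect matching: every item
    belongs to exactly one pair.  Pairs carry identifiers (``pair_ids``)
    so that form-construction bookkeeping can refer to them.
    """

    def __init__(
        self,
        items: Sequence[ItemParameters],
        pair_of: Mapping[str, str] | None = None,
        pair_ids: Mapping[str, tuple[str, str]] | None = None,
    ) -> None:
        self.items: list[ItemParameters] = list(items)
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        self._index = {it.item_id: it for it in self.items}

        if pair_of is not None:
            pair_of = dict(pair_of)
            self._check_matching(pair_of)
        self.pair_of: dict[str, str] | None = pair_of

        if pair_ids is not None:
            if pair_of is None:
                raise ValueError("pair_ids given without pair_of")
            self.pair_ids = {str(k): (v[0], v[1]) for k, v in pair_ids.items()}
        elif pair_of is not None:
            self.pair_ids = {
                f"P{i + 1:02d}": pr for i, pr in enumerate(self._ordered_pairs(pair_of))
            }
        else:
            self.pair_ids = None

    def _check_matching(self, pair_of: dict[str, str]) -> None:
        ids = set(self.item_ids)
        if set(pair_of) != ids:
            raise ValueError("pairing must cover every item exactly once")
        for a, b in pair_of.items():
            if b not in ids or a == b or pair_of.get(b) != a:
                raise ValueError(f"pairing is not a symmetric perfect matching at {a!r}")

    def _ordered_pairs(self, pair_of: Mapping[str, str]) -> list[tuple[str, str]]:
        seen: set[str] = set()
        out = []
        for it in self.items:
            i = it.item_id
            if i in seen:
                continue
            j = pair_of[i]
            seen.update((i, j))
            out.append((i, j))
        return out

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> ItemParameters:
        return self._index[item_id]

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def pairs(self) -> list[tuple[str, tuple[str, str]]]:
        """Return ``(pair_id, (item_id_1, item_id_2))`` in bank order."""
        if self.pair_of is None:
            raise ValueError("bank has no content pairing")
        return [(pid, pr) for pid, pr in self.pair_ids.items()]

    def subset(self, item_ids: Iterable[str]) -> list[ItemParameters]:
        return [self[i] for i in item_ids]


@dataclass(frozen=True)
class ResponsePattern:
    """Ordered responses (0..4, ``None`` for missing) aligned with item ids."""

    item_ids: tuple[str, ...]
    responses: tuple[int | None, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "responses", tuple(self.responses))
        if len(self.item_ids) != len(self.responses):
            raise ValueError("item_ids and responses must have equal length")
        for r in self.responses:
            if r is not None and (not isinstance(r, (int, np.integer)) or not 0 <= r <= 4):
                raise ValueError(f"responses must be integers in 0..4 or None, got {r!r}")
        if all(r is None for r in self.responses):
            raise ValueError("at least one non-missing response is required")

    def as_array(self) -> np.ndarray:
        """Responses as an int array with ``-1`` marking missing values."""
        return np.array([MISSING if r is None else int(r) for r in self.responses])


@dataclass(frozen=True)
class ThetaEstimate:
    """A scored administration: ML theta, SE, and convergence metadata.

    ``se`` is ``nan`` when ``boundary`` is true (the likelihood has no
    interior maximiser, so the information-based SE is undefined).
    """

    theta: float
    se: float
    n_items_used: int
    boundary: bool
    loglik: float


# ---------------------------------------------------------------------------
# Elementary model quantities (scalar API)
# ---------------------------------------------------------------------------

def cumulative_prob(theta: float, item: ItemParameters, k: int) -> float:
    """P*(X >= k | theta): probability of responding in category ``k`` or above.

    Defined for ``k`` in ``0..5`` with the boundary conventions
    ``P*_0 = 1`` and ``P*_5 = 0``.
    """
    if not 0 <= k <= N_CATEGORIES:
        raise ValueError(f"k must be in 0..{N_CATEGORIES}, got {k}")
    if k == 0:
        return 1.0
    if k == N_CATEGORIES:
        return 0.0
    return float(expit(item.a * (theta - item.b[k - 1])))


def category_prob(theta: float, item: ItemParameters, k: int) -> float:
    """P(X = k | theta) = P*_k - P*_{k+1}, for ``k`` in ``0..4``."""
    if not 0 <= k < N_CATEGORIES:
        raise ValueError(f"k must be in 0..{N_CATEGORIES - 1}, got {k}")
    return cumulative_prob(theta, item, k) - cumulative_prob(theta, item, k + 1)


# ---------------------------------------------------------------------------
# Vectorised internals shared by likelihood, information and scoring
# ---------------------------------------------------------------------------

def _star_probs(theta: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cumulative probabilities P*_k, padded with the k=0 and k=5 conventions.

    theta : shape (T,);  a : (I,);  b : (I, 4)  ->  returns (T, I, 6).
    """
    t = np.asarray(theta, dtype=float).reshape(-1, 1, 1)
    core = expit(a[None, :, None] * (t - b[None, :, :]))  # (T, I, 4)
    T, I = core.shape[0], core.shape[1]
    out = np.empty((T, I, N_CATEGORIES + 1))
    out[:, :, 0] = 1.0
    out[:, :, 1:-1] = core
    out[:, :, -1] = 0.0
    return out


def _cat_probs(theta: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (T, I, 5)."""
    star = _star_probs(theta, a, b)
    return star[:, :, :-1] - star[:, :, 1:]


def _item_information_grid(theta: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Expected Fisher information per item on a theta grid, shape (T, I).

    Uses dP*_k/dtheta = a P*_k (1 - P*_k) and
    I_i(theta) = sum_k (dP_k/dtheta)^2 / P_k.
    """
    star = _star_probs(theta, a, b)
    dstar = a[None, :, None] * star * (1.0 - star)  # derivative; 0 at the padded ends
    p = star[:, :, :-1] - star[:, :, 1:]
    dp = dstar[:, :, :-1] - dstar[:, :, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, dp * dp / np.where(p > 0, p, 1.0), 0.0)
    return terms.sum(axis=2)


def _bank_arrays(items: Sequence[ItemParameters]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    return a, b


def item_information(theta: float, item: ItemParameters) -> float:
    """Expected Fisher information contributed by one item at ``theta``."""
    a, b = _bank_arrays([item])
    return float(_item_information_grid(np.atleast_1d(theta), a, b)[0, 0])


def test_information(theta_grid: Sequence[float], items: Sequence[ItemParameters]) -> np.ndarray:
    """Test information: pointwise sum of item informations over a form."""
    grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("theta grid must be non-empty")
    if len(items) == 0:
        return np.zeros_like(grid)
    a, b = _bank_arrays(items)
    return _item_information_grid(grid, a, b).sum(axis=1)


def response_loglik(pattern: ResponsePattern, bank: ItemBank, theta: float) -> float:
    """Log-likelihood of a response pattern at ``theta`` (missing dropped)."""
    missing = [i for i in pattern.item_ids if i not in bank]
    if missing:
        raise KeyError(f"items not in bank: {missing}")
    items = bank.subset(pattern.item_ids)
    a, b = _bank_arrays(items)
    resp = pattern.as_array()
    probs = _cat_probs(np.atleast_1d(theta), a, b)[0]  # (I, 5)
    mask = resp != MISSING
    p = probs[np.arange(len(items))[mask], resp[mask]]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(p)))


# ---------------------------------------------------------------------------
# Maximum-likelihood scoring
# ---------------------------------------------------------------------------

class FormScorer:
    """Maximum-likelihood theta scorer for a fixed set of items.

    Precomputes the item-parameter arrays for a form so that many response
    patterns can be scored cheaply.  The maximiser is located by a coarse
    grid scan (0.1 steps across the scale) followed by bounded Brent
    refinement inside the bracketing grid interval, to a tolerance of 1e-6;
    the GRM log-likelihood is unimodal in theta for a fixed pattern, so the
    grid seed guards only against numerically flat stretches.
    """

    def __init__(
        self,
        items: Sequence[ItemParameters],
        bounds: tuple[float, float] = THETA_BOUNDS,
        grid_step: float = 0.1,
        xtol: float = 1e-6,
    ) -> None:
        if len(items) == 0:
            raise ValueError("scorer needs at least one item")
        self.items = list(items)
        self.item_ids = [it.item_id for it in self.items]
        self.bounds = (float(bounds[0]), float(bounds[1]))
        self.xtol = float(xtol)
        self._a, self._b = _bank_arrays(self.items)
        n_grid = int(round((self.bounds[1] - self.bounds[0]) / grid_step)) + 1
        self._grid = np.linspace(self.bounds[0], self.bounds[1], n_grid)
        # log category probabilities on the seed grid, (T, I, 5)
        with np.errstate(divide="ignore"):
            self._log_probs_grid = np.log(_cat_probs(self._grid, self._a, self._b))

    # -- likelihood ---------------------------------------------------------------
    def loglik(self, responses: np.ndarray, theta: float) -> float:
        """Log-likelihood of one integer response vector (-1 = missing)."""
        probs = _cat_probs(np.atleast_1d(theta), self._a, self._b)[0]
        mask = responses != MISSING
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(probs[np.where(mask)[0], responses[mask]])))

    def _grid_logliks(self, resp_matrix: np.ndarray) -> np.ndarray:
        """Seed-grid log-likelihood for many patterns at once, (N, T)."""
        n, I = resp_matrix.shape
        T = self._grid.size
        out = np.zeros((n, T))
        cols = np.arange(I)
        for j in range(n):
            resp = resp_matrix[j]
            mask = resp != MISSING
            out[j] = self._log_probs_grid[:, cols[mask], resp[mask]].sum(axis=1)
        return out

    # -- scoring ------------------------------------------------------------------
    def score(self, responses: Sequence[int | None] | np.ndarray) -> ThetaEstimate:
        resp = np.array(
            [MISSING if r is None else int(r) for r in np.asarray(responses, dtype=object)]
        )
        return self._score_one(resp)

    def score_many(self, resp_matrix: np.ndarray) -> list[ThetaEstimate]:
        """Score each row of an (N, I) integer response matrix (-1 = missing)."""
        resp_matrix = np.asarray(resp_matrix, dtype=int)
        seeds = np.argmax(self._grid_logliks(resp_matrix), axis=1)
        return [self._score_one(resp_matrix[j], seed_idx=seeds[j]) for j in range(resp_matrix.shape[0])]

    def _score_one(self, resp: np.ndarray, seed_idx: int | None = None) -> ThetaEstimate:
        mask = resp != MISSING
        n_used = int(mask.sum())
        if n_used == 0:
            raise ValueError("cannot score an all-missing response pattern")
        lo, hi = self.bounds
        used = resp[mask]
        # Extreme patterns: the likelihood is monotone, no interior maximiser.
        if np.all(used == 0):
            return ThetaEstimate(lo, float("nan"), n_used, True, self.loglik(resp, lo))
        if np.all(used == N_CATEGORIES - 1):
            return ThetaEstimate(hi, float("nan"), n_used, True, self.loglik(resp, hi))

        if seed_idx is None:
            cols = np.arange(resp.size)
            gl = self._log_probs_grid[:, cols[mask], resp[mask]].sum(axis=1)
            seed_idx = int(np.argmax(gl))
        # Bracket one grid step either side of the best grid point.
        left = self._grid[max(seed_idx - 1, 0)]
        right = self._grid[min(seed_idx + 1, self._grid.size - 1)]
        if left == right:  # single-point grid
            theta_hat = float(left)
        else:
            res = minimize_scalar(
                lambda t: -self.loglik(resp, t),
                bounds=(left, right),
                method="bounded",
                options={"xatol": self.xtol},
            )
            theta_hat = float(res.x)

        boundary = theta_hat <= lo + self.xtol or theta_hat >= hi - self.xtol
        if boundary:
            theta_hat = lo if theta_hat < 0 else hi
            se = float("nan")
        else:
            info = float(
                _item_information_grid(np.atleast_1d(theta_hat), self._a[mask], self._b[mask]).sum()
            )
            se = 1.0 / np.sqrt(info) if info > 0 else float("nan")
        return ThetaEstimate(theta_hat, se, n_used, boundary, self.loglik(resp, theta_hat))


def estimate_theta(pattern: ResponsePattern, bank: ItemBank) -> ThetaEstimate:
    """Score one response pattern against a bank by maximum likelihood.

    Missing responses are dropped from the likelihood; ``n_items_used``
    records how many items contributed.  Raises ``KeyError`` if the pattern
    refers to an item absent from the bank.
    """
    missing = [i for i in pattern.item_ids if i not in bank]
    if missing:
        raise KeyError(f"items not in bank: {missing}")
    scorer = FormScorer(bank.subset(pattern.item_ids))
    return scorer.score(pattern.responses)
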
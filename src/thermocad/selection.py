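"""Wrapper feature selection with NSGA-III and single-objective baselines.

The selection task is posed over binary genomes (one bit per feature).  The
multi-objective variant (NSGA-III) minimizes the inner cross-validated
misclassification rate and the selected-feature fraction simultaneously,
returning a Pareto front; GA, PSO and DE baselines minimize the scalarized
objective J = error + w * nf_frac.  The inner fitness classifier is a
5-nearest-neighbour vote under seeded stratified 5-fold cross-validation,
which keeps evaluation fast and deterministic for a fixed seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "Objectives",
    "SelectionResult",
    "SubsetEvaluator",
    "evaluate_subset",
    "fast_non_dominated_sort",
    "das_dennis_reference_points",
    "nsga3_select",
    "ga_select",
    "pso_select",
    "de_select",
    "objective_vs_k_curve",
]


@dataclass(frozen=True)
class Objectives:
    """Inner-CV misclassification rate and selected-feature fraction, both in [0, 1]."""

    error: float
    nf_frac: float

    def scalar(self, w: float = 0.01) -> float:
        return self.error + w * self.nf_frac


@dataclass
class SelectionResult:
    pareto: list  # list of (bits array, Objectives), mutually non-dominated
    best_scalar: float
    chosen_bits: np.ndarray
    chosen_subset: list[str]
    history: list[float]  # best-so-far scalar objective per generation
    runtime: float
    method: str


class SubsetEvaluator:
    """Cached fitness evaluation of feature subsets.

    ``error`` is the mean misclassification of KNN(k=5) over a seeded
    stratified 5-fold inner CV restricted to the selected columns; the table
    is standardized once up front.  An empty genome is repaired to the single
    best univariate feature (largest absolute two-class t statistic).
    """

    def __init__(self, table: pd.DataFrame, labels: np.ndarray, seed: int = 0,
                 inner_folds: int = 5, knn_k: int = 5):
        X = np.asarray(table, dtype=float)
        self.names = list(table.columns)
        mu, sd = X.mean(0), X.std(0)
        sd[sd == 0] = 1.0
        self.X = (X - mu) / sd
        self.y = np.asarray(labels)
        self.seed = seed
        self.cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        self.knn_k = knn_k
        self._cache: dict[bytes, Objectives] = {}
        self.n_features = X.shape[1]
        # univariate ranking for genome repair
        g0, g1 = self.X[self.y == self.y[0]], self.X[self.y != self.y[0]]
        denom = np.sqrt(g0.var(0) / max(len(g0), 1) + g1.var(0) / max(len(g1), 1))
        denom[denom == 0] = 1.0
        self.best_univariate = int(np.argmax(np.abs(g0.mean(0) - g1.mean(0)) / denom))

    def repair(self, bits: np.ndarray) -> np.ndarray:
        bits = np.asarray(bits, dtype=bool).copy()
        if not bits.any():
            warnings.warn("empty subset repaired to the best univariate feature", RuntimeWarning)
            bits[self.best_univariate] = True
        return bits

    def __call__(self, bits: np.ndarray) -> Objectives:
        bits = self.repair(bits)
        key = np.packbits(bits).tobytes()
        if key not in self._cache:
            knn = KNeighborsClassifier(n_neighbors=self.knn_k)
            acc = cross_val_score(knn, self.X[:, bits], self.y, cv=self.cv).mean()
            self._cache[key] = Objectives(error=float(1.0 - acc),
                                          nf_frac=float(bits.sum()) / self.n_features)
        return self._cache[key]

    def decode(self, bits: np.ndarray) -> list[str]:
        return [n for n, b in zip(self.names, bits) if b]


def evaluate_subset(bits, table: pd.DataFrame, labels, inner_cv: int = 5,
                    seed: int = 0) -> Objectives:
    """One-shot subset fitness (see :class:`SubsetEvaluator`)."""
    return SubsetEvaluator(table, labels, seed=seed, inner_folds=inner_cv)(np.asarray(bits, bool))


# ---------------------------------------------------------------------------
# non-dominated sorting and NSGA-III machinery
# ---------------------------------------------------------------------------

def fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fronts of mutually non-dominated rows of F (minimization), best first."""
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    # dominated[i, j] True if i dominates j
    le = (F[:, None, :] <= F[None, :, :]).all(-1)
    lt = (F[:, None, :] < F[None, :, :]).any(-1)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        front = np.flatnonzero(remaining & (n_dominators == 0))
        if front.size == 0:  # numerical safety: ties everywhere
            front = np.flatnonzero(remaining)
        fronts.append(front)
        remaining[front] = False
        n_dominators = n_dominators - dom[front].sum(axis=0)
    return fronts


def das_dennis_reference_points(n_obj: int, n_points: int) -> np.ndarray:
    """Uniform simplex reference directions with about ``n_points`` members."""
    p = 1
    while _n_partitions(n_obj, p + 1) <= n_points:
        p += 1
    return np.array(list(_simplex(n_obj, p, p))) / p


def _n_partitions(n_obj: int, p: int) -> int:
    from math import comb
    return comb(p + n_obj - 1, n_obj - 1)


def _simplex(n_obj, p, left):
    if n_obj == 1:
        yield (left,)
        return
    for i in range(left + 1):
        for rest in _simplex(n_obj - 1, p, left - i):
            yield (i,) + rest


def _niching_select(F: np.ndarray, fronts: list[np.ndarray], n_select: int,
                    refs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """NSGA-III environmental selection: fill whole fronts, then niche the last."""
    chosen: list[int] = []
    fi = 0
    while fi < len(fronts) and len(chosen) + fronts[fi].size <= n_select:
        chosen.extend(fronts[fi].tolist())
        fi += 1
    if len(chosen) == n_select or fi >= len(fronts):
        return np.asarray(chosen[:n_select], dtype=int)
    last = fronts[fi]
    pool = np.concatenate([np.asarray(chosen, dtype=int), last]) if chosen else last

    # normalize objectives over the candidate pool by ideal/nadir
    ideal = F[pool].min(axis=0)
    nadir = F[pool].max(axis=0)
    span = np.where(nadir - ideal > 1e-12, nadir - ideal, 1.0)
    Fn = (F - ideal) / span

    # associate: perpendicular distance to each reference direction
    unit = refs / np.linalg.norm(refs, axis=1, keepdims=True)

    def associate(idx):
        proj = Fn[idx] @ unit.T                       # (n, R)
        perp = np.linalg.norm(Fn[idx][:, None, :] - proj[..., None] * unit[None], axis=2)
        return perp.argmin(axis=1), perp.min(axis=1)

    niche_count = np.zeros(len(refs), dtype=int)
    if chosen:
        assoc_chosen, _ = associate(np.asarray(chosen, dtype=int))
        for a in assoc_chosen:
            niche_count[a] += 1
    assoc_last, dist_last = associate(last)

    remaining = list(range(last.size))
    while len(chosen) < n_select and remaining:
        counts = np.array([niche_count[assoc_last[i]] for i in remaining])
        cand_refs = {assoc_last[i] for i in remaining}
        min_count = min(niche_count[r] for r in cand_refs)
        # among least-crowded niches pick the member closest to its reference line
        elig = [i for i in remaining if niche_count[assoc_last[i]] == min_count]
        best = min(elig, key=lambda i: (dist_last[i], i))
        chosen.append(int(last[best]))
        niche_count[assoc_last[best]] += 1
        remaining.remove(best)
    return np.asarray(chosen, dtype=int)


def _dedupe_front(bits_list, objs) -> list:
    seen, out = set(), []
    for b, o in zip(bits_list, objs):
        key = b.tobytes()
        if key not in seen:
            seen.add(key)
            out.append((b.copy(), o))
    return out


def nsga3_select(table: pd.DataFrame, labels, seed: int = 0, n_pop: int = 30,
                 n_gen: int = 20, p_crossover: float = 0.7, p_mutation: float = 0.4,
                 mutation_rate: float = 0.1, scalar_w: float = 0.01,
                 evaluator: SubsetEvaluator | None = None) -> SelectionResult:
    """Multi-objective subset search (error, feature fraction) with NSGA-III.

    Per generation, 2*round(p_crossover*n_pop/2) offspring are produced by
    uniform crossover of randomly selected parents and round(p_mutation*n_pop)
    mutants by per-bit flips at ``mutation_rate``; parents and offspring are
    merged and reduced back to ``n_pop`` by non-dominated sorting plus
    reference-point niching on normalized objectives.
    """
    t0 = time.perf_counter()
    if n_pop < 4:
        raise ValueError("population must be at least 4")
    ev = evaluator or SubsetEvaluator(table, labels, seed=seed)
    _check_classes(ev.y)
    rng = np.random.default_rng(seed)
    d = ev.n_features
    refs = das_dennis_reference_points(2, n_pop)

    pop = [ev.repair(rng.random(d) < 0.5) for _ in range(n_pop)]
    objs = [ev(b) for b in pop]
    history = [min(o.scalar(scalar_w) for o in objs)]

    n_cross = 2 * round(p_crossover * n_pop / 2)
    n_mut = round(p_mutation * n_pop)
    for _ in range(n_gen):
        children = []
        for _ in range(n_cross // 2):
            i, j = rng.choice(n_pop, size=2, replace=False)
            m = rng.random(d) < 0.5
            c1 = np.where(m, pop[i], pop[j])
            c2 = np.where(m, pop[j], pop[i])
            children += [ev.repair(c1), ev.repair(c2)]
        for _ in range(n_mut):
            b = pop[rng.integers(n_pop)].copy()
            flip = rng.random(d) < mutation_rate
            b ^= flip
            children.append(ev.repair(b))
        all_pop = pop + children
        all_obj = objs + [ev(b) for b in children]
        F = np.array([[o.error, o.nf_frac] for o in all_obj])
        fronts = fast_non_dominated_sort(F)
        sel = _niching_select(F, fronts, n_pop, refs, rng)
        pop = [all_pop[i] for i in sel]
        objs = [all_obj[i] for i in sel]
        history.append(min(history[-1], min(o.scalar(scalar_w) for o in objs)))

    F = np.array([[o.error, o.nf_frac] for o in objs])
    front0 = fast_non_dominated_sort(F)[0]
    pareto = _dedupe_front([pop[i] for i in front0], [objs[i] for i in front0])
    scalars = [o.scalar(scalar_w) for _, o in pareto]
    best_i = int(np.argmin(scalars))
    bits = pareto[best_i][0]
    return SelectionResult(
        pareto=pareto, best_scalar=float(scalars[best_i]), chosen_bits=bits,
        chosen_subset=ev.decode(bits), history=history,
        runtime=time.perf_counter() - t0, method="nsga3",
    )


def _check_classes(y: np.ndarray) -> None:
    vals, counts = np.unique(y, return_counts=True)
    if vals.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 10:
        warnings.warn("fewer than 10 samples in a class; inner CV may be unstable", RuntimeWarning)


def _single_objective_result(method, ev, best_bits, best_J, history, t0, scalar_w,
                             archive) -> SelectionResult:
    bits_list = [b for b, _ in archive]
    objs = [o for _, o in archive]
    F = np.array([[o.error, o.nf_frac] for o in objs])
    front0 = fast_non_dominated_sort(F)[0]
    pareto = _dedupe_front([bits_list[i] for i in front0], [objs[i] for i in front0])
    return SelectionResult(
        pareto=pareto, best_scalar=float(best_J), chosen_bits=best_bits,
        chosen_subset=ev.decode(best_bits), history=history,
        runtime=time.perf_counter() - t0, method=method,
    )


def ga_select(table: pd.DataFrame, labels, seed: int = 0, n_pop: int = 30,
              n_gen: int = 20, pc: float = 0.8, pm: float = 0.3, mu: float = 0.02,
              selection_pressure: float = 8.0, scalar_w: float = 0.01,
              evaluator: SubsetEvaluator | None = None) -> SelectionResult:
    """Elitist genetic algorithm minimizing J = error + w * nf_frac.

    Roulette-wheel parent selection with exponential pressure, uniform
    crossover for 2*round(pc*n_pop/2) offspring, round(pm*n_pop) mutants with
    per-bit flip rate ``mu``; parents, offspring and mutants are merged and
    truncated to ``n_pop``, so the best J is non-increasing.
    """
    t0 = time.perf_counter()
    if n_pop < 4:
        raise ValueError("population must be at least 4")
    ev = evaluator or SubsetEvaluator(table, labels, seed=seed)
    _check_classes(ev.y)
    rng = np.random.default_rng(seed)
    d = ev.n_features

    pop = [ev.repair(rng.random(d) < 0.5) for _ in range(n_pop)]
    J = np.array([ev(b).scalar(scalar_w) for b in pop])
    archive = [(b, ev(b)) for b in pop]
    history = [float(J.min())]
    n_cross = 2 * round(pc * n_pop / 2)
    n_mut = round(pm * n_pop)
    for _ in range(n_gen):
        worst = J.max() if J.max() > 0 else 1.0
        probs = np.exp(-selection_pressure * J / worst)
        probs /= probs.sum()
        children = []
        for _ in range(n_cross // 2):
            i, j = rng.choice(n_pop, size=2, replace=False, p=probs)
            mask = rng.random(d) < 0.5
            children += [ev.repair(np.where(mask, pop[i], pop[j])),
                         ev.repair(np.where(mask, pop[j], pop[i]))]
        for _ in range(n_mut):
            b = pop[rng.choice(n_pop, p=probs)].copy()
            b ^= rng.random(d) < mu
            children.append(ev.repair(b))
        all_pop = pop + children
        all_J = np.concatenate([J, [ev(b).scalar(scalar_w) for b in children]])
        archive += [(b, ev(b)) for b in children]
        order = np.argsort(all_J, kind="stable")[:n_pop]
        pop = [all_pop[i] for i in order]
        J = all_J[order]
        history.append(float(min(history[-1], J.min())))
    best = int(np.argmin(J))
    return _single_objective_result("ga", ev, pop[best], J[best], history, t0,
                                    scalar_w, archive)


def pso_select(table: pd.DataFrame, labels, seed: int = 0, n_pop: int = 20,
               n_gen: int = 20, inertia: float = 1.0, damping: float = 0.99,
               c1: float = 2.0, c2: float = 2.0, scalar_w: float = 0.01,
               evaluator: SubsetEvaluator | None = None) -> SelectionResult:
    """Binary feature selection by particle swarm: continuous positions in
    [0, 1]^d thresholded at 0.5, inertia-damped velocity updates."""
    t0 = time.perf_counter()
    ev = evaluator or SubsetEvaluator(table, labels, seed=seed)
    _check_classes(ev.y)
    rng = np.random.default_rng(seed)
    d = ev.n_features

    X = rng.random((n_pop, d))
    V = np.zeros((n_pop, d))
    decode = lambda x: ev.repair(x > 0.5)
    J = np.array([ev(decode(x)).scalar(scalar_w) for x in X])
    archive = [(decode(x), ev(decode(x))) for x in X]
    pbest_x, pbest_J = X.copy(), J.copy()
    g = int(np.argmin(J))
    gbest_x, gbest_J = X[g].copy(), float(J[g])
    history = [gbest_J]
    w = inertia
    vmax = 0.5
    for _ in range(n_gen):
        r1, r2 = rng.random((n_pop, d)), rng.random((n_pop, d))
        V = w * V + c1 * r1 * (pbest_x - X) + c2 * r2 * (gbest_x[None] - X)
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, 0.0, 1.0)
        J = np.array([ev(decode(x)).scalar(scalar_w) for x in X])
        archive += [(decode(x), ev(decode(x))) for x in X]
        better = J < pbest_J
        pbest_x[better], pbest_J[better] = X[better], J[better]
        g = int(np.argmin(pbest_J))
        if pbest_J[g] < gbest_J:
            gbest_J, gbest_x = float(pbest_J[g]), pbest_x[g].copy()
        history.append(gbest_J)
        w *= damping
    return _single_objective_result("pso", ev, decode(gbest_x), gbest_J, history,
                                    t0, scalar_w, archive)


def de_select(table: pd.DataFrame, labels, seed: int = 0, n_pop: int = 20,
              n_gen: int = 20, beta_min: float = 0.2, beta_max: float = 0.8,
              p_cr: float = 0.2, scalar_w: float = 0.01,
              evaluator: SubsetEvaluator | None = None) -> SelectionResult:
    """Differential evolution (rand/1/bin) on continuous positions in [0, 1]^d,
    thresholded at 0.5 into feature bits; greedy one-to-one replacement."""
    t0 = time.perf_counter()
    ev = evaluator or SubsetEvaluator(table, labels, seed=seed)
    _check_classes(ev.y)
    rng = np.random.default_rng(seed)
    d = ev.n_features

    X = rng.random((n_pop, d))
    decode = lambda x: ev.repair(x > 0.5)
    J = np.array([ev(decode(x)).scalar(scalar_w) for x in X])
    archive = [(decode(x), ev(decode(x))) for x in X]
    history = [float(J.min())]
    for _ in range(n_gen):
        for i in range(n_pop):
            a, b, c = rng.choice([k for k in range(n_pop) if k != i], size=3, replace=False)
            beta = rng.uniform(beta_min, beta_max, size=d)
            mutant = X[a] + beta * (X[b] - X[c])
            cross = rng.random(d) < p_cr
            cross[rng.integers(d)] = True
            trial = np.clip(np.where(cross, mutant, X[i]), 0.0, 1.0)
            Jt = ev(decode(trial)).scalar(scalar_w)
            archive.append((decode(trial), ev(decode(trial))))
            if Jt <= J[i]:
                X[i], J[i] = trial, Jt
        history.append(float(min(history[-1], J.min())))
    best = int(np.argmin(J))
    return _single_objective_result("de", ev, decode(X[best]), float(J[best]),
                                    history, t0, scalar_w, archive)


def objective_vs_k_curve(result: SelectionResult, epsilon: float = 0.01) -> pd.DataFrame:
    """Best error per subset size along the Pareto set, with the elbow flagged.

    The elbow is the smallest k at which the marginal error decrease per
    additional feature (to the next represented subset size) falls below
    ``epsilon`` — past it, extra features buy less than ``epsilon`` each.
    """
    if not result.pareto:
        raise ValueError("empty Pareto set")
    per_k: dict[int, float] = {}
    for bits, obj in result.pareto:
        k = int(np.asarray(bits).sum())
        per_k[k] = min(per_k.get(k, np.inf), obj.error)
    ks = sorted(per_k)
    errs = [per_k[k] for k in ks]
    elbow = ks[-1]
    for idx, k in enumerate(ks[:-1]):
        marginal = (errs[idx] - errs[idx + 1]) / (ks[idx + 1] - k)
        if marginal <= epsilon:
            elbow = k
            break
    return pd.DataFrame({"k": ks, "error": errs, "is_elbow": [k == elbow for k in ks]})
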
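"""Randomized partial-profile choice design generation and scoring.

The generator emulates what commercial conjoint software does when asked for
a "balanced and near-orthogonal" design: every task shows a fixed-size subset
of the attributes, each alternative assigns one level per shown attribute,
prohibited level pairs never co-occur within an alternative, and a greedy
swap optimizer pushes the design towards level balance (each level of an
attribute appearing equally often) and pairwise orthogonality (each pair of
levels across two attributes co-occurring equally often).

Scores are integer shortfalls: for balance, the max-minus-min level frequency
summed over attributes; for orthogonality, the max-minus-min co-occurrence
count summed over attribute pairs.  Both are zero exactly when the design is
perfectly balanced/orthogonal, and the optimizer never increases their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CodingMap
from .core import InfeasibleDesignError, Prohibition, SpecError, StudySpec

_MAX_SAMPLING_TRIES = 2000


@dataclass(frozen=True)
class DesignTask:
    """One choice task: a shown-attribute subset and its alternatives."""

    shown: tuple[str, ...]
    alternatives: tuple[dict, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shown", tuple(self.shown))
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        shown = set(self.shown)
        for alt in self.alternatives:
            if set(alt) != shown:
                raise SpecError(
                    "alternative attribute subset differs from the task's shown set"
                )
        seen = [tuple(sorted(a.items())) for a in self.alternatives]
        if len(set(seen)) != len(seen):
            raise SpecError("a task may not contain two identical alternatives")


@dataclass(frozen=True)
class ChoiceDesign:
    """A versioned questionnaire: an ordered list of choice tasks."""

    version_id: int
    tasks: tuple[DesignTask, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tasks", tuple(self.tasks))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: version, task, alt, one column per attribute."""
        rows = []
        for t, task in enumerate(self.tasks, start=1):
            for a, alt in enumerate(task.alternatives, start=1):
                rows.append({"version": self.version_id, "task": t, "alt": a, **alt})
        return pd.DataFrame(rows)


@dataclass
class DesignDiagnostics:
    """Balance and orthogonality bookkeeping for a design (or pooled set)."""

    level_frequency: dict
    balance_score: float
    cooccurrence: dict
    orthogonality_score: float
    d_efficiency: float | None = None

    @property
    def combined_score(self) -> float:
        return self.balance_score + self.orthogonality_score


# ---------------------------------------------------------------------------
# internal integer representation
#
# L is an int array (tasks, alternatives, attributes); entry -1 means the
# attribute is not shown in that task, otherwise it is the level index.


def _prohibition_index(spec: StudySpec) -> list[tuple[int, int, int, int]]:
    name_to_idx = {a.name: i for i, a in enumerate(spec.attributes)}
    out = []
    for p in spec.prohibitions:
        ka, kb = name_to_idx[p.attribute_a], name_to_idx[p.attribute_b]
        la = spec.attributes[ka].level_index(p.level_a)
        lb = spec.attributes[kb].level_index(p.level_b)
        out.append((ka, la, kb, lb))
    return out


def _row_allowed(row: np.ndarray, prohibitions) -> bool:
    for ka, la, kb, lb in prohibitions:
        if row[ka] == la and row[kb] == lb:
            return False
    return True


def _design_to_array(design: ChoiceDesign, spec: StudySpec) -> np.ndarray:
    T = len(design.tasks)
    A = len(design.tasks[0].alternatives) if T else 0
    K = len(spec.attributes)
    name_to_idx = {a.name: i for i, a in enumerate(spec.attributes)}
    L = np.full((T, A, K), -1, dtype=int)
    for t, task in enumerate(design.tasks):
        for a, alt in enumerate(task.alternatives):
            for attr_name, level in alt.items():
                k = name_to_idx[attr_name]
                L[t, a, k] = spec.attributes[k].level_index(level)
    return L


def _array_to_design(L: np.ndarray, spec: StudySpec, version_id: int, seed: int) -> ChoiceDesign:
    tasks = []
    for t in range(L.shape[0]):
        shown_idx = [k for k in range(L.shape[2]) if L[t, 0, k] >= 0]
        shown = tuple(spec.attributes[k].name for k in shown_idx)
        alts = tuple(
            {
                spec.attributes[k].name: spec.attributes[k].levels[L[t, a, k]]
                for k in shown_idx
            }
            for a in range(L.shape[1])
        )
        tasks.append(DesignTask(shown, alts))
    return ChoiceDesign(version_id=version_id, tasks=tuple(tasks), seed=seed)


class _Scorer:
    """Incrementally maintained level frequencies, co-occurrences and scores."""

    def __init__(self, L: np.ndarray, spec: StudySpec):
        self.L = L
        self.r = [a.n_levels for a in spec.attributes]
        K = len(self.r)
        self.freq = [[0] * rk for rk in self.r]
        self.cooc = {
            (s, t): [[0] * self.r[t] for _ in range(self.r[s])]
            for s in range(K)
            for t in range(s + 1, K)
        }
        for task in L:
            for row in task:
                shown = [k for k in range(K) if row[k] >= 0]
                for k in shown:
                    self.freq[k][row[k]] += 1
                for i, s in enumerate(shown):
                    for t in shown[i + 1:]:
                        self.cooc[(s, t)][row[s]][row[t]] += 1
        self.bal_contrib = [max(f) - min(f) for f in self.freq]
        self.orth_contrib = {
            pair: self._span(mat) for pair, mat in self.cooc.items()
        }
        self.balance = sum(self.bal_contrib)
        self.orthogonality = sum(self.orth_contrib.values())

    @staticmethod
    def _span(mat) -> int:
        flat = [v for row in mat for v in row]
        return max(flat) - min(flat)

    def change(self, t: int, a: int, k: int, new_level: int) -> None:
        """Commit one cell change and update all affected scores."""
        old = self.L[t, a, k]
        if old == new_level:
            return
        self.freq[k][old] -= 1
        self.freq[k][new_level] += 1
        self.balance -= self.bal_contrib[k]
        self.bal_contrib[k] = max(self.freq[k]) - min(self.freq[k])
        self.balance += self.bal_contrib[k]
        row = self.L[t, a]
        for m in range(len(self.r)):
            if m == k or row[m] < 0:
                continue
            pair = (k, m) if k < m else (m, k)
            mat = self.cooc[pair]
            if k < m:
                mat[old][row[m]] -= 1
                mat[new_level][row[m]] += 1
            else:
                mat[row[m]][old] -= 1
                mat[row[m]][new_level] += 1
            self.orthogonality -= self.orth_contrib[pair]
            self.orth_contrib[pair] = self._span(mat)
            self.orthogonality += self.orth_contrib[pair]
        self.L[t, a, k] = new_level

    @property
    def combined(self) -> int:
        return self.balance + self.orthogonality


# ---------------------------------------------------------------------------
# generation


def _choose_subsets(spec: StudySpec, rng: np.random.Generator) -> list[list[int]]:
    """Rotate 4-of-7 (generally m-of-K) subsets, balancing appearance counts."""
    K = len(spec.attributes)
    counts = np.zeros(K)
    subsets = []
    for _ in range(spec.n_tasks_per_respondent):
        order = np.lexsort((rng.random(K), counts))
        subset = sorted(int(k) for k in order[: spec.n_attributes_shown])
        counts[subset] += 1
        subsets.append(subset)
    return subsets


def _sample_task(
    spec: StudySpec,
    subset: list[int],
    prohibitions,
    rng: np.random.Generator,
) -> np.ndarray:
    K = len(spec.attributes)
    rows = np.full((spec.n_alternatives, K), -1, dtype=int)
    for a in range(spec.n_alternatives):
        for _ in range(_MAX_SAMPLING_TRIES):
            row = np.full(K, -1, dtype=int)
            for k in subset:
                row[k] = rng.integers(spec.attributes[k].n_levels)
            if not _row_allowed(row, prohibitions):
                continue
            if any(np.array_equal(row, rows[b]) for b in range(a)):
                continue
            rows[a] = row
            break
        else:
            shown_names = {spec.attributes[k].name for k in subset}
            blocking = [
                p
                for p in spec.prohibitions
                if p.attribute_a in shown_names and p.attribute_b in shown_names
            ]
            raise InfeasibleDesignError(
                "could not sample a feasible alternative for attribute subset "
                f"{sorted(shown_names)}; blocking prohibitions: {blocking}"
            )
    return rows


def _greedy_improve(
    L: np.ndarray,
    spec: StudySpec,
    prohibitions,
    max_passes: int,
) -> list[int]:
    """Deterministic sweep of single-cell level changes.

    A move is accepted only if it strictly lowers balance + orthogonality and
    leaves neither component above its value at the start, so the improved
    design never scores worse than the random design it began from on either
    criterion.  Returns the combined-score trace (one entry per accepted
    move), which is strictly decreasing.
    """
    scorer = _Scorer(L, spec)
    bal_cap, orth_cap = scorer.balance, scorer.orthogonality
    history = [scorer.combined]
    T, A, K = L.shape
    for _ in range(max_passes):
        improved = False
        for t in range(T):
            for a in range(A):
                for k in range(K):
                    cur = L[t, a, k]
                    if cur < 0:
                        continue
                    for lv in range(spec.attributes[k].n_levels):
                        if lv == cur:
                            continue
                        row = L[t, a].copy()
                        row[k] = lv
                        if not _row_allowed(row, prohibitions):
                            continue
                        if any(
                            np.array_equal(row, L[t, b])
                            for b in range(A)
                            if b != a
                        ):
                            continue
                        before = scorer.combined
                        scorer.change(t, a, k, lv)
                        if (
                            scorer.combined < before
                            and scorer.balance <= bal_cap
                            and scorer.orthogonality <= orth_cap
                        ):
                            history.append(scorer.combined)
                            improved = True
                            cur = lv
                        else:
                            scorer.change(t, a, k, cur)
        if not improved:
            break
    return history


def generate_design(
    spec: StudySpec,
    version_id: int = 1,
    seed: int = 0,
    optimize_passes: int = 8,
    restarts: int = 1,
) -> ChoiceDesign:
    """Generate one prohibition-respecting, near-balanced questionnaire version.

    Starts from uniform random prohibition-respecting tasks (with attribute
    subsets rotated to balance attribute appearances) and applies the greedy
    swap improver.  ``restarts`` independent random starts may be tried; the
    best-scoring result is kept.  Deterministic given ``seed``.
    """
    if restarts < 1:
        raise SpecError("restarts must be at least 1")
    rng = np.random.default_rng(seed)
    prohibitions = _prohibition_index(spec)
    best_L = None
    best_score = None
    for _ in range(restarts):
        subsets = _choose_subsets(spec, rng)
        L = np.stack(
            [_sample_task(spec, subset, prohibitions, rng) for subset in subsets]
        )
        if optimize_passes > 0:
            _greedy_improve(L, spec, prohibitions, optimize_passes)
        score = _Scorer(L, spec).combined
        if best_score is None or score < best_score:
            best_L, best_score = L, score
    return _array_to_design(best_L, spec, version_id, seed)


def improve_design(
    design: ChoiceDesign,
    spec: StudySpec,
    max_passes: int = 20,
) -> tuple[ChoiceDesign, list[int]]:
    """Run the greedy improver on an existing design.

    Returns the improved design and the monotone (strictly decreasing)
    combined-score trace, starting at the input design's score.
    """
    L = _design_to_array(design, spec)
    history = _greedy_improve(L, spec, _prohibition_index(spec), max_passes)
    return _array_to_design(L, spec, design.version_id, design.seed), history


def generate_version_set(
    spec: StudySpec,
    n_versions: int | None = None,
    master_seed: int = 0,
    optimize_passes: int = 8,
) -> list[ChoiceDesign]:
    """Independent questionnaire versions with seeds derived from one master."""
    if n_versions is None:
        n_versions = spec.n_versions
    if n_versions < 1:
        raise SpecError("n_versions must be at least 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_versions)
    return [
        generate_design(
            spec,
            version_id=v + 1,
            seed=int(seeds[v]),
            optimize_passes=optimize_passes,
        )
        for v in range(n_versions)
    ]


# ---------------------------------------------------------------------------
# scoring


def _diagnostics_from_scorer(
    scorer: _Scorer, spec: StudySpec, scale: float = 1.0
) -> tuple[dict, dict]:
    freq = {
        (attr.name, lv): scorer.freq[k][j] / scale if scale != 1.0 else scorer.freq[k][j]
        for k, attr in enumerate(spec.attributes)
        for j, lv in enumerate(attr.levels)
    }
    cooc = {}
    for (s, t), mat in scorer.cooc.items():
        sa, ta = spec.attributes[s], spec.attributes[t]
        for i, la in enumerate(sa.levels):
            for j, lb in enumerate(ta.levels):
                v = mat[i][j] / scale if scale != 1.0 else mat[i][j]
                cooc[((sa.name, la), (ta.name, lb))] = v
    return freq, cooc


def _d_efficiency(L: np.ndarray, spec: StudySpec) -> float:
    coding = CodingMap(spec)
    rows = []
    for task in L:
        for row in task:
            shown = {
                spec.attributes[k].name: spec.attributes[k].levels[row[k]]
                for k in range(len(spec.attributes))
                if row[k] >= 0
            }
            rows.append(coding.code_alternative(shown))
    X = np.asarray(rows)
    if X.size == 0:
        return 0.0
    M = X.T @ X / len(X)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return 0.0
    return float(np.exp(logdet / coding.n_parameters))


def score_design(design: ChoiceDesign, spec: StudySpec) -> DesignDiagnostics:
    """Exact frequency/co-occurrence tables and shortfall scores for a design."""
    L = _design_to_array(design, spec)
    prohibitions = _prohibition_index(spec)
    for t in range(L.shape[0]):
        for a in range(L.shape[1]):
            if not _row_allowed(L[t, a], prohibitions):
                raise SpecError(
                    f"design task {t + 1} alternative {a + 1} violates a prohibition"
                )
    scorer = _Scorer(L, spec)
    freq, cooc = _diagnostics_from_scorer(scorer, spec)
    return DesignDiagnostics(
        level_frequency=freq,
        balance_score=scorer.balance,
        cooccurrence=cooc,
        orthogonality_score=scorer.orthogonality,
        d_efficiency=_d_efficiency(L, spec),
    )


def score_version_set(designs: list[ChoiceDesign], spec: StudySpec) -> DesignDiagnostics:
    """Pooled diagnostics over several versions, on the per-version scale.

    Frequencies and co-occurrences are averaged over versions (raw pooled
    counts divided by the number of versions) so the scores are directly
    comparable to those of a single version.
    """
    if not designs:
        raise SpecError("need at least one design to score")
    arrays = [_design_to_array(d, spec) for d in designs]
    L = np.concatenate(arrays, axis=0)
    scorer = _Scorer(L, spec)
    n = len(designs)
    freq, cooc = _diagnostics_from_scorer(scorer, spec, scale=float(n))
    return DesignDiagnostics(
        level_frequency=freq,
        balance_score=scorer.balance / n,
        cooccurrence=cooc,
        orthogonality_score=scorer.orthogonality / n,
        d_efficiency=_d_efficiency(L, spec),
    )


def designs_to_frame(designs: list[ChoiceDesign]) -> pd.DataFrame:
    """Stack several versions into one long-format export table."""
    return pd.concat([d.to_frame() for d in designs], ignore_index=True)
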
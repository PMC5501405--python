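"""D-efficient choice-design construction.

A design is a list of choice sets, each pairing two fictitious inhaler
profiles (the respondent's current inhaler is appended at survey time, not
stored in the design). Designs are scored by D-efficiency — the normalized
determinant of the multinomial-logit Fisher information at prior coefficients
— and assembled by coordinate exchange from random starts, then split into
equally sized blocks balanced on level frequencies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .schema import (
    AttributeSpec,
    Profile,
    code_profile,
    coded_names,
    validate_profile,
)


@dataclass
class ChoiceSet:
    """One question: an ordered pair of fictitious inhaler profiles."""

    set_id: int
    block_id: int
    alternatives: tuple[Profile, Profile]

    def __post_init__(self):
        if self.alternatives[0] == self.alternatives[1]:
            raise SchemaError(
                f"choice set {self.set_id}: the two alternatives are identical"
            )


@dataclass
class DesignDiagnostics:
    d_efficiency: float
    level_balance: dict
    pairwise_correlation: pd.DataFrame
    duplicate_set_count: int

    def to_dict(self) -> dict:
        corr = self.pairwise_correlation
        return {
            "d_efficiency": self.d_efficiency,
            "level_balance": self.level_balance,
            "pairwise_correlation": {
                "columns": list(corr.columns),
                "values": [
                    [None if not np.isfinite(v) else round(float(v), 10) for v in row]
                    for row in corr.to_numpy()
                ],
            },
            "duplicate_set_count": self.duplicate_set_count,
        }


@dataclass
class Design:
    """A blocked choice design together with its attribute schema."""

    choice_sets: list[ChoiceSet]
    attributes: list[AttributeSpec]
    n_blocks: int = 1
    diagnostics: DesignDiagnostics | None = None

    def __post_init__(self):
        ids = [cs.set_id for cs in self.choice_sets]
        if len(set(ids)) != len(ids):
            raise SchemaError("set_ids are not unique")
        sizes = self.block_sizes()
        if sizes and len(set(sizes.values())) > 1:
            raise SchemaError(f"unequal block sizes: {sizes}")

    @property
    def n_sets(self) -> int:
        return len(self.choice_sets)

    def block_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cs in self.choice_sets:
            sizes[cs.block_id] = sizes.get(cs.block_id, 0) + 1
        return sizes

    def sets_in_block(self, block_id: int) -> list[ChoiceSet]:
        return [cs for cs in self.choice_sets if cs.block_id == block_id]


def coded_alternatives(design: Design) -> np.ndarray:
    """Coded design array of shape (n_sets, 2, p)."""
    rows = [
        [code_profile(p, design.attributes) for p in cs.alternatives]
        for cs in design.choice_sets
    ]
    return np.asarray(rows)


def _info_from_coded(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    # X: (n_sets, J, p). Sum over sets of X' (diag(p) - p p') X at MNL probs.
    eta = X @ beta
    eta = eta - eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    probs = w / w.sum(axis=1, keepdims=True)
    xbar = np.einsum("sj,sjp->sp", probs, X)
    Xc = X - xbar[:, None, :]
    return np.einsum("sj,sjp,sjq->pq", probs, Xc, Xc)


def mnl_information_matrix(design: Design, beta: Sequence[float]) -> np.ndarray:
    """Fisher information of the MNL over the design's choice sets at beta."""
    X = coded_alternatives(design)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[2],):
        raise ValueError(
            f"beta has length {beta.size}, design codes {X.shape[2]} parameters"
        )
    M = _info_from_coded(X, beta)
    return 0.5 * (M + M.T)


def d_efficiency(design: Design, beta: Sequence[float] | None = None) -> float:
    """det(information)^(1/p) / n_sets; 0 for a singular information matrix."""
    if beta is None:
        beta = np.zeros(len(coded_names(design.attributes)))
    M = mnl_information_matrix(design, beta)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        return 0.0
    return float(np.exp(logdet / M.shape[0]) / design.n_sets)


def _random_coded_design(
    cand: np.ndarray, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices (n_sets, 2) into the candidate profile set, no within-set dupes."""
    n = cand.shape[0]
    idx = np.empty((n_sets, 2), dtype=int)
    for s in range(n_sets):
        i = rng.integers(n)
        j = rng.integers(n)
        while j == i:
            j = rng.integers(n)
        idx[s] = (i, j)
    return idx


def random_design(
    attrs: Sequence[AttributeSpec],
    n_sets: int,
    seed: int | np.random.Generator,
    n_blocks: int = 1,
) -> Design:
    """A uniformly random design (distinct profiles within each set)."""
    from .schema import enumerate_full_factorial

    rng = np.random.default_rng(seed)
    candidates = enumerate_full_factorial(attrs)
    cand = np.asarray([code_profile(p, attrs) for p in candidates])
    idx = _random_coded_design(cand, n_sets, rng)
    sets = [
        ChoiceSet(s, 0, (candidates[idx[s, 0]], candidates[idx[s, 1]]))
        for s in range(n_sets)
    ]
    d = Design(sets, list(attrs), n_blocks=1)
    if n_blocks > 1:
        d = block_design(d, n_blocks, seed=rng.integers(2**31 - 1))
    return d


def _set_info(Xs: np.ndarray, beta: np.ndarray) -> np.ndarray:
    # Xs: (J, p) — one choice set's contribution to the information matrix.
    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    probs = w / w.sum()
    Xc = Xs - probs @ Xs
    return (probs[:, None] * Xc).T @ Xc


def search_design(
    attrs: Sequence[AttributeSpec],
    n_sets: int,
    n_blocks: int = 1,
    beta: Sequence[float] | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    max_sweeps: int = 50,
) -> Design:
    """Coordinate-exchange search for a D-efficient blocked design.

    From each random start, every (set, alternative, attribute) coordinate is
    revisited in turn and every other level of that attribute is tried in its
    place; a move is kept only if it strictly improves D-efficiency (the
    incumbent wins ties), never leaves two identical profiles in one set, and
    never duplicates a whole choice set (as an unordered profile pair) —
    respondents should not face the same question twice. Sweeps repeat until
    a full pass makes no move. The best design over ``n_restarts`` starts is
    blocked and returned. Deterministic given seed.
    """
    attrs = list(attrs)
    if n_sets % n_blocks != 0:
        raise ConfigError(
            f"n_sets={n_sets} is not divisible by n_blocks={n_blocks}"
        )
    p = len(coded_names(attrs))
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    if beta.shape != (p,):
        raise ValueError(f"beta has length {beta.size}, schema codes {p} parameters")

    # levels[s, a, k] = level index of attribute k in alternative a of set s
    n_levels = [len(a.levels) for a in attrs]

    # Precompute, per attribute, the slice of coded columns it owns.
    col_slices = []
    start = 0
    for a in attrs:
        width = 1 if a.kind == "continuous" else len(a.coded_levels)
        col_slices.append(slice(start, start + width))
        start += width
    per_attr_codes = []
    for a, sl in zip(attrs, col_slices):
        block = np.zeros((len(a.levels), sl.stop - sl.start))
        for i, lvl in enumerate(a.levels):
            if a.kind == "continuous":
                block[i, 0] = float(lvl)
            else:
                for j, coded_lvl in enumerate(a.coded_levels):
                    block[i, j] = 1.0 if lvl == coded_lvl else 0.0
        per_attr_codes.append(block)

    def levels_to_coded(levels: np.ndarray) -> np.ndarray:
        # levels: (n_sets, 2, n_attrs) -> (n_sets, 2, p)
        X = np.zeros(levels.shape[:2] + (p,))
        for k, sl in enumerate(col_slices):
            X[..., sl] = per_attr_codes[k][levels[..., k]]
        return X

    def logdet_per_p(M: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(M)
        return logdet / p if sign > 0 and np.isfinite(logdet) else -np.inf

    def set_signature(levels_s: np.ndarray) -> frozenset:
        return frozenset((tuple(levels_s[0]), tuple(levels_s[1])))

    rng = np.random.default_rng(seed)
    best_levels = None
    best_score = -np.inf
    for _ in range(n_restarts):
        levels = np.stack(
            [rng.integers(L, size=(n_sets, 2)) for L in n_levels], axis=-1
        )
        # repair within-set duplicates and duplicated whole sets by redrawing;
        # when the factorial is too small for all-distinct sets, give up on
        # whole-set uniqueness after a bounded number of attempts
        signatures: set[frozenset] = set()
        for s in range(n_sets):
            for _attempt in range(200):
                ok_within = not np.array_equal(levels[s, 0], levels[s, 1])
                if ok_within and set_signature(levels[s]) not in signatures:
                    break
                levels[s, 1] = [rng.integers(L) for L in n_levels]
            else:
                while np.array_equal(levels[s, 0], levels[s, 1]):
                    levels[s, 1] = [rng.integers(L) for L in n_levels]
            signatures.add(set_signature(levels[s]))
        X = levels_to_coded(levels)
        set_infos = np.stack([_set_info(X[s], beta) for s in range(n_sets)])
        M = set_infos.sum(axis=0)
        score = logdet_per_p(M)
        for _sweep in range(max_sweeps):
            improved = False
            for s in range(n_sets):
                others = {
                    set_signature(levels[t]) for t in range(n_sets) if t != s
                }
                for alt in range(2):
                    for k in range(len(attrs)):
                        incumbent = levels[s, alt, k]
                        for lvl in range(n_levels[k]):
                            if lvl == incumbent:
                                continue
                            levels[s, alt, k] = lvl
                            if (
                                np.array_equal(levels[s, 0], levels[s, 1])
                                or set_signature(levels[s]) in others
                            ):
                                continue
                            Xs = levels_to_coded(levels[s : s + 1])[0]
                            trial_info = _set_info(Xs, beta)
                            trial = logdet_per_p(M - set_infos[s] + trial_info)
                            if trial > score + 1e-12:
                                M = M - set_infos[s] + trial_info
                                set_infos[s] = trial_info
                                score = trial
                                incumbent = lvl
                                improved = True
                        levels[s, alt, k] = incumbent
            if not improved:
                break
        if best_levels is None or score > best_score:
            best_score = score
            best_levels = levels.copy()

    sets = []
    for s in range(n_sets):
        profs = tuple(
            Profile(
                {
                    a.name: a.levels[best_levels[s, alt, k]]
                    for k, a in enumerate(attrs)
                }
            )
            for alt in range(2)
        )
        sets.append(ChoiceSet(s, 0, profs))
    design = Design(sets, attrs, n_blocks=1)
    if n_blocks > 1:
        design = block_design(design, n_blocks, seed=int(rng.integers(2**31 - 1)))
    design.diagnostics = design_diagnostics(design)
    return design


def _block_imbalance(design: Design, assignment: np.ndarray, n_blocks: int) -> float:
    """Max deviation of per-block level frequencies from perfect balance."""
    per_block = design.n_sets // n_blocks
    worst = 0.0
    for a in design.attributes:
        levels = list(a.levels)
        expected = per_block * 2 / len(levels)
        counts = np.zeros((n_blocks, len(levels)))
        for cs, b in zip(design.choice_sets, assignment):
            for prof in cs.alternatives:
                counts[b, levels.index(prof[a.name])] += 1
        worst = max(worst, float(np.abs(counts - expected).max()))
    return worst


def block_design(design: Design, n_blocks: int, seed: int = 0) -> Design:
    """Split a design into equal blocks, balancing level frequencies.

    Greedy pairwise-swap descent on the maximum per-block deviation of level
    frequencies from perfect balance, from a seeded random equal split.
    """
    if design.n_sets % n_blocks != 0:
        raise ConfigError(
            f"{design.n_sets} sets cannot form {n_blocks} equal blocks"
        )
    if n_blocks == 1:
        sets = [ChoiceSet(cs.set_id, 0, cs.alternatives) for cs in design.choice_sets]
        return Design(sets, design.attributes, n_blocks=1,
                      diagnostics=design.diagnostics)

    rng = np.random.default_rng(seed)
    per_block = design.n_sets // n_blocks
    order = rng.permutation(design.n_sets)
    assignment = np.empty(design.n_sets, dtype=int)
    for rank, s in enumerate(order):
        assignment[s] = rank // per_block

    score = _block_imbalance(design, assignment, n_blocks)
    improved = True
    while improved and score > 0:
        improved = False
        for i in range(design.n_sets):
            for j in range(i + 1, design.n_sets):
                if assignment[i] == assignment[j]:
                    continue
                assignment[i], assignment[j] = assignment[j], assignment[i]
                trial = _block_imbalance(design, assignment, n_blocks)
                if trial < score - 1e-12:
                    score = trial
                    improved = True
                else:
                    assignment[i], assignment[j] = assignment[j], assignment[i]

    sets = [
        ChoiceSet(cs.set_id, int(b), cs.alternatives)
        for cs, b in zip(design.choice_sets, assignment)
    ]
    return Design(sets, design.attributes, n_blocks=n_blocks,
                  diagnostics=design.diagnostics)


def design_diagnostics(design: Design) -> DesignDiagnostics:
    """Level balance, coded-column correlations, duplicates, D-efficiency at 0."""
    balance: dict = {}
    for a in design.attributes:
        counts = {str(l): 0 for l in a.levels}
        for cs in design.choice_sets:
            for prof in cs.alternatives:
                counts[str(prof[a.name])] += 1
        balance[a.name] = counts

    X = coded_alternatives(design).reshape(design.n_sets * 2, -1)
    names = coded_names(design.attributes)
    sd = X.std(axis=0)
    constant = sd < 1e-12
    if constant.any():
        warnings.warn(
            "constant coded column(s) "
            + ", ".join(n for n, c in zip(names, constant) if c)
            + "; correlations reported as missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.where(np.outer(~constant, ~constant), corr, np.nan)
    corr_df = pd.DataFrame(corr, index=names, columns=names)

    seen: dict[frozenset, int] = {}
    dupes = 0
    for cs in design.choice_sets:
        key = frozenset(p.key() for p in cs.alternatives)
        if key in seen:
            dupes += 1
        else:
            seen[key] = cs.set_id

    return DesignDiagnostics(
        d_efficiency=d_efficiency(design),
        level_balance=balance,
        pairwise_correlation=corr_df,
        duplicate_set_count=dupes,
    )


def design_to_frame(design: Design) -> pd.DataFrame:
    """Long representation: one row per set × alternative."""
    rows = []
    for cs in design.choice_sets:
        for alt_id, prof in zip(("A", "B"), cs.alternatives):
            row = {"block_id": cs.block_id, "set_id": cs.set_id, "alt_id": alt_id}
            row.update({a.name: prof[a.name] for a in design.attributes})
            rows.append(row)
    return pd.DataFrame(rows)


def write_design(design: Design, csv_path, diagnostics_path=None) -> None:
    design_to_frame(design).to_csv(csv_path, index=False)
    if diagnostics_path is not None:
        diag = design.diagnostics or design_diagnostics(design)
        with open(diagnostics_path, "w") as fh:
            json.dump(diag.to_dict(), fh, indent=2)


def read_design(csv_path, attrs: Sequence[AttributeSpec]) -> Design:
    df = pd.read_csv(csv_path)
    attrs = list(attrs)
    sets = []
    for (set_id, block_id), grp in df.groupby(["set_id", "block_id"], sort=True):
        grp = grp.sort_values("alt_id")
        profs = []
        for _, row in grp.iterrows():
            assignment = {}
            for a in attrs:
                v = row[a.name]
                assignment[a.name] = float(v) if a.kind == "continuous" else v
            prof = Profile(assignment)
            validate_profile(prof, attrs)
            profs.append(prof)
        if len(profs) != 2:
            raise SchemaError(f"set {set_id}: expected 2 alternatives, got {len(profs)}")
        sets.append(ChoiceSet(int(set_id), int(block_id), (profs[0], profs[1])))
    n_blocks = df["block_id"].nunique()
    return Design(sets, attrs, n_blocks=int(n_blocks))
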
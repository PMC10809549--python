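"""Signed reversal distance, sorting scenarios and ancestral gene orders.

The unit of analysis is a signed permutation: the order of synteny blocks
along one chromosomal element, each block carrying an orientation. The
minimum number of reversals (paracentric inversions) transforming one
order into another is computed from the breakpoint graph via the
Hannenhalli-Pevzner formula

    d = n + 1 - c + h + f

where ``c`` counts alternating cycles, ``h`` hurdles (unoriented
components whose positions form a single arc on the closed frame) and
``f`` flags a fortress (an odd number of hurdles, all of them
super-hurdles). An exhaustive breadth-first oracle over the whole group
of signed permutations (n <= 8) is provided to arbitrate correctness.

Ancestral arrangements on the fixed four-taxon mosquito tree are inferred
by a tree-aware greedy search in the spirit of MGR: reversals that bring
one genome closer to all the others are applied first, cherries are
merged before the root, and events are attributed to branches as they
are undone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import KaryoshuffleError, ValidationError

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


def _validate_elements(elements) -> tuple[int, ...]:
    elems = tuple(int(x) for x in elements)
    if any(x == 0 for x in elems):
        raise ValidationError("signed permutation elements must be non-zero")
    if sorted(abs(x) for x in elems) != list(range(1, len(elems) + 1)):
        raise ValidationError(
            "absolute values must be a permutation of 1..n, got "
            f"{sorted(abs(x) for x in elems)}"
        )
    return elems


@dataclass(frozen=True)
class SignedPermutation:
    """A linear, signed order of blocks 1..n."""

    elements: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "elements", _validate_elements(self.elements))

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @classmethod
    def identity(cls, n: int) -> "SignedPermutation":
        return cls(tuple(range(1, n + 1)))

    def inverse(self) -> "SignedPermutation":
        inv = [0] * len(self.elements)
        for pos, x in enumerate(self.elements, start=1):
            if x > 0:
                inv[x - 1] = pos
            else:
                inv[-x - 1] = -pos
        return SignedPermutation(tuple(inv))

    def reflected(self) -> "SignedPermutation":
        """Whole-permutation reversal with sign flip (reading the arm
        from the other telomere)."""
        return SignedPermutation(tuple(-x for x in reversed(self.elements)))


@dataclass(frozen=True)
class BreakpointGraph:
    n: int
    cycles: int
    hurdles: int
    fortress: int


@dataclass(frozen=True)
class ReversalScenario:
    """An ordered list of inclusive index pairs (i, j); each step reverses
    and sign-flips elements i..j (0-based)."""

    steps: tuple[tuple[int, int], ...]
    policy: str = "smallest_first"

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class SpeciesTree:
    """Fixed rooted 4-taxon topology ((s1,s2),(s3,s4)) with divergence
    times in million years."""

    cherry1: tuple[str, str] = ("An_albimanus", "An_coluzzii")
    cherry2: tuple[str, str] = ("Cx_quinquefasciatus", "Ae_aegypti")
    t_root_my: float = 134.6
    t_cherry2_my: float = 62.3
    t_cherry1_my: float | None = None

    def __post_init__(self):
        if self.t_root_my <= 0 or self.t_cherry2_my <= 0:
            raise ValidationError("divergence times must be positive")

    @property
    def species(self) -> tuple[str, str, str, str]:
        return (*self.cherry1, *self.cherry2)

    @property
    def branches(self) -> tuple[str, ...]:
        return (*self.species, "cherry1", "cherry2")


# ---------------------------------------------------------------------------
# Elementary operations on tuples
# ---------------------------------------------------------------------------

def _as_tuple(p) -> tuple[int, ...]:
    if isinstance(p, SignedPermutation):
        return p.elements
    return _validate_elements(p)


def reverse_segment(p, i: int, j: int) -> tuple[int, ...]:
    """Reverse and sign-flip elements i..j inclusive (0-based)."""
    t = _as_tuple(p)
    if not 0 <= i <= j < len(t):
        raise ValidationError(f"reversal ({i},{j}) out of range for n={len(t)}")
    return t[:i] + tuple(-x for x in reversed(t[i : j + 1])) + t[j + 1 :]


def relabel(source, target) -> tuple[int, ...]:
    """Rename elements so that ``target`` becomes the identity; the
    distance of the result to the identity equals d(source, target)."""
    s, t = _as_tuple(source), _as_tuple(target)
    if len(s) != len(t):
        raise ValidationError("permutations have different element sets")
    m: dict[int, int] = {}
    for pos, x in enumerate(t, start=1):
        m[x] = pos
        m[-x] = -pos
    return tuple(m[x] for x in s)


# ---------------------------------------------------------------------------
# Breakpoint graph and Hannenhalli-Pevzner distance
# ---------------------------------------------------------------------------

def _graph_stats(p: tuple[int, ...]) -> tuple[int, int, int]:
    """(cycles, hurdles, fortress) of the framed breakpoint graph."""
    n = len(p)
    # frame with 0 and n+1, expand +x -> (2x-1, 2x), -x -> (2|x|, 2|x|-1)
    u = [0] * (2 * n + 2)
    k = 1
    for x in p:
        if x > 0:
            u[k] = 2 * x - 1
            u[k + 1] = 2 * x
        else:
            u[k] = -2 * x
            u[k + 1] = -2 * x - 1
        k += 2
    u[2 * n + 1] = 2 * n + 1
    pos = [0] * (2 * n + 2)
    for i, v in enumerate(u):
        pos[v] = i

    # cycles: black edges join positions (2i, 2i+1); gray edges join the
    # positions of values (2i, 2i+1)
    visited = [False] * (2 * n + 2)
    cycles = 0
    for s in range(0, 2 * n + 2, 2):
        if visited[s]:
            continue
        cycles += 1
        cur = s
        while not visited[cur]:
            visited[cur] = True
            b = cur ^ 1
            visited[b] = True
            cur = pos[u[b] ^ 1]

    # gray edges as sorted position pairs; drop adjacencies (trivial cycles)
    grays: list[tuple[int, int]] = []
    for v in range(0, 2 * n + 2, 2):
        a, b = pos[v], pos[v + 1]
        if a > b:
            a, b = b, a
        if b == a + 1 and a % 2 == 0:
            continue  # adjacency, coincides with a black edge
        grays.append((a, b))
    g = len(grays)
    if g == 0:
        return cycles, 0, 0

    # connected components of the edge-interleaving graph (union-find)
    parent = list(range(g))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(g):
        ia, ja = grays[a]
        for b in range(a + 1, g):
            ib, jb = grays[b]
            if (ia < ib < ja < jb) or (ib < ia < jb < ja):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb

    comp_oriented: dict[int, bool] = {}
    comp_positions: dict[int, list[int]] = {}
    for idx, (i, j) in enumerate(grays):
        root = find(idx)
        comp_oriented[root] = comp_oriented.get(root, False) or ((i + j) % 2 == 0)
        comp_positions.setdefault(root, []).extend((i, j))

    unoriented = [c for c, ori in comp_oriented.items() if not ori]
    if not unoriented:
        return cycles, 0, 0

    # hurdles: close the frame into a circle; an unoriented component is a
    # hurdle iff its positions form one contiguous arc among the positions
    # of all unoriented components
    items = sorted(
        (posn, comp) for comp in unoriented for posn in comp_positions[comp]
    )
    labels = [comp for _, comp in items]

    def run_counts(lab: list[int]) -> dict[int, int]:
        m = len(lab)
        counts: dict[int, int] = {}
        starts = 0
        for k2 in range(m):
            if lab[k2] != lab[k2 - 1]:
                counts[lab[k2]] = counts.get(lab[k2], 0) + 1
                starts += 1
        if starts == 0 and m:
            counts[lab[0]] = 1
        return counts

    rc = run_counts(labels)
    hurdle_set = [c for c in unoriented if rc.get(c, 0) == 1]
    h = len(hurdle_set)
    fortress = 0
    if h and h % 2 == 1:
        all_super = True
        for hd in hurdle_set:
            reduced = [l for l in labels if l != hd]
            rc2 = run_counts(reduced)
            protected = any(
                rc.get(c, 0) > 1 and rc2.get(c, 0) == 1
                for c in unoriented
                if c != hd
            )
            if not protected:
                all_super = False
                break
        if all_super:
            fortress = 1
    return cycles, h, fortress


def breakpoint_graph(p) -> BreakpointGraph:
    """Cycle/hurdle/fortress decomposition of a signed permutation."""
    t = _as_tuple(p)
    c, h, f = _graph_stats(t)
    return BreakpointGraph(n=len(t), cycles=c, hurdles=h, fortress=f)


def inversion_distance(p, target=None) -> int:
    """Minimum number of reversals transforming ``p`` into ``target``
    (identity by default): n + 1 - c + h + f."""
    t = _as_tuple(p)
    if target is not None:
        t = relabel(t, target)
    n = len(t)
    if n == 0:
        return 0
    c, h, f = _graph_stats(t)
    return n + 1 - c + h + f


def count_breakpoints(p, q) -> int:
    """Number of framed signed adjacencies of ``p`` absent from ``q``;
    (a,b) and (-b,-a) are the same adjacency."""
    s, t = _as_tuple(p), _as_tuple(q)
    if len(s) != len(t):
        raise ValidationError("permutations have different element sets")

    def adjacencies(perm: tuple[int, ...]) -> set[tuple[int, int]]:
        n = len(perm)
        seq = (0,) + perm + (n + 1,)
        out = set()
        for a, b in zip(seq, seq[1:]):
            out.add(min((a, b), (-b, -a)))
        return out

    return len(adjacencies(s) - adjacencies(t))


# ---------------------------------------------------------------------------
# Exhaustive BFS oracle (n <= 8)
# ---------------------------------------------------------------------------

_ORACLE_TABLES: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_ORACLE_MAX_N = 8


def _pack(rows: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(rows).view(np.int64).ravel()


def _unpack(keys: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(keys).view(np.int8).reshape(-1, 8)


def _oracle_table(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distance-from-identity for every signed permutation of 1..n,
    computed by one breadth-first sweep of the reversal graph. States are
    packed 8 x int8 -> int64. Memoized per n."""
    if n in _ORACLE_TABLES:
        return _ORACLE_TABLES[n]
    ident = np.zeros((1, 8), dtype=np.int8)
    ident[0, :n] = np.arange(1, n + 1, dtype=np.int8)
    frontier = ident
    level_keys = [_pack(ident).copy()]
    level_dist = [np.zeros(1, dtype=np.uint8)]
    visited = level_keys[0].copy()
    revs = [(i, j) for i in range(n) for j in range(i + 1, n + 1)]
    d = 0
    while True:
        d += 1
        parts = []
        for i, j in revs:
            new = frontier.copy()
            new[:, i:j] = -frontier[:, i:j][:, ::-1]
            pk = _pack(new)
            idx = np.searchsorted(visited, pk)
            idx[idx == len(visited)] = 0
            parts.append(pk[visited[idx] != pk])
        fresh = np.unique(np.concatenate(parts))
        if fresh.size == 0:
            break
        level_keys.append(fresh)
        level_dist.append(np.full(fresh.size, d, dtype=np.uint8))
        visited = np.union1d(visited, fresh)
        frontier = _unpack(fresh)
    keys = np.concatenate(level_keys)
    dist = np.concatenate(level_dist)
    order = np.argsort(keys)
    table = (keys[order], dist[order])
    _ORACLE_TABLES[n] = table
    return table


def all_signed_permutations(n: int):
    """Iterate every signed permutation of 1..n (n! * 2^n of them)."""
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield tuple(s * x for s, x in zip(signs, perm))


def bfs_oracle_distance(p, target=None, max_n: int = _ORACLE_MAX_N) -> int:
    """Exact reversal distance by exhaustive breadth-first search.

    Independent of the breakpoint-graph formula; refuses n > ``max_n``
    (the full group has n! * 2^n states).
    """
    t = _as_tuple(p)
    if target is not None:
        t = relabel(t, target)
    n = len(t)
    if n == 0:
        return 0
    if n > max_n or n > _ORACLE_MAX_N:
        raise KaryoshuffleError(f"BFS oracle refuses n={n} > {min(max_n, _ORACLE_MAX_N)}")
    keys, dist = _oracle_table(n)
    row = np.zeros((1, 8), dtype=np.int8)
    row[0, :n] = t
    key = _pack(row)[0]
    i = int(np.searchsorted(keys, key))
    if i >= len(keys) or keys[i] != key:
        raise KaryoshuffleError("permutation missing from oracle table")
    return int(dist[i])


def oracle_distance_map(n: int) -> dict[tuple[int, ...], int]:
    """Distance-from-identity for all signed permutations of n (n <= 8)."""
    if n > _ORACLE_MAX_N:
        raise KaryoshuffleError(f"BFS oracle refuses n={n}")
    keys, dist = _oracle_table(n)
    rows = _unpack(keys)
    return {
        tuple(int(x) for x in rows[i, :n]): int(dist[i]) for i in range(len(keys))
    }


# ---------------------------------------------------------------------------
# Sorting scenarios
# ---------------------------------------------------------------------------

def sorting_scenario(source, target=None, policy: str = "smallest_first") -> ReversalScenario:
    """A minimum-length reversal sequence from ``source`` to ``target``.

    Under ``smallest_first`` the shortest-span distance-reducing reversal
    is taken at each step (ties: leftmost), mirroring a search that
    detects the smallest inversions first; ``any`` takes the first
    distance-reducing reversal in (i, j) scan order.
    """
    if policy not in ("smallest_first", "any"):
        raise ValueError(f"unknown policy {policy!r}")
    cur = _as_tuple(source)
    if target is not None:
        cur = relabel(cur, target)
    n = len(cur)
    steps: list[tuple[int, int]] = []
    d = inversion_distance(cur)
    while d > 0:
        chosen = None
        if policy == "smallest_first":
            candidates = (
                (i, i + span - 1)
                for span in range(1, n + 1)
                for i in range(0, n - span + 1)
            )
        else:
            candidates = ((i, j) for i in range(n) for j in range(i, n))
        for i, j in candidates:
            nxt = reverse_segment(cur, i, j)
            if inversion_distance(nxt) == d - 1:
                chosen = (i, j, nxt)
                break
        if chosen is None:  # cannot happen: some reversal always reduces d
            raise KaryoshuffleError("no distance-reducing reversal found")
        steps.append((chosen[0], chosen[1]))
        cur = chosen[2]
        d -= 1
    return ReversalScenario(steps=tuple(steps), policy=policy)


def apply_scenario(p, scenario: ReversalScenario) -> tuple[int, ...]:
    cur = _as_tuple(p)
    for i, j in scenario.steps:
        cur = reverse_segment(cur, i, j)
    return cur


# ---------------------------------------------------------------------------
# Ancestral reconstruction (tree-aware greedy, MGR-like)
# ---------------------------------------------------------------------------

def _check_same_elements(perms: dict[str, tuple[int, ...]]):
    sets = {sp: tuple(sorted(abs(x) for x in p)) for sp, p in perms.items()}
    ref = next(iter(sets.values()))
    bad = [sp for sp, s in sets.items() if s != ref]
    if bad:
        raise ValidationError(f"mismatched block sets across species: {bad}")


def _converge_cherry(
    genomes: dict[str, tuple[int, ...]],
    pair: tuple[str, str],
    others: list[str],
    counts: dict[str, int],
) -> None:
    """Apply reversals to the two sister genomes until they agree.

    Every step must reduce the sister-sister distance by one (so the loop
    terminates at the cherry node); among such reversals the one that
    maximally decreases the summed distance to all other genomes is taken
    (ties: smallest span, then leftmost, then species order). Events
    shared by both sisters are untouched here - they belong to deeper
    branches.
    """
    a, b = pair
    n = len(genomes[a])
    while genomes[a] != genomes[b]:
        best = None  # key = (-delta, span, i, species_rank)
        for rank, (tag, other_tag) in enumerate(((a, b), (b, a))):
            g = genomes[tag]
            partner = genomes[other_tag]
            d_pair = inversion_distance(g, partner)
            base_out = sum(inversion_distance(g, genomes[o]) for o in others)
            for span in range(1, n + 1):
                for i in range(0, n - span + 1):
                    j = i + span - 1
                    g2 = reverse_segment(g, i, j)
                    if inversion_distance(g2, partner) != d_pair - 1:
                        continue
                    out = sum(inversion_distance(g2, genomes[o]) for o in others)
                    delta = 1 + (base_out - out)
                    key = (-delta, span, i, rank)
                    if best is None or key < best[0]:
                        best = (key, tag, g2)
        _, tag, g2 = best
        genomes[tag] = g2
        counts[tag] += 1


def reconstruct_ancestor(
    perms: dict, tree: SpeciesTree
) -> tuple[SignedPermutation, dict[str, int]]:
    """Infer the ancestral block order of one chromosomal element and the
    number of reversals on each branch of the fixed 4-taxon tree.

    Cherries are merged first (leaf-branch events undone greedily), then
    the two cherry ancestors are walked toward each other along a
    minimum scenario; the meeting point - the inferred root - splits the
    remaining steps between the two internal branches as evenly as
    possible, the odd step going to cherry1. The root's exact position on
    the internal path is not identifiable from four leaves, so the
    balanced split bounds the placement error by half the internal-path
    length. Branch counts always sum to the total scenario length.
    """
    missing = [sp for sp in tree.species if sp not in perms]
    if missing:
        raise ValidationError(f"permutations missing for species: {missing}")
    genomes = {sp: _as_tuple(perms[sp]) for sp in tree.species}
    _check_same_elements(genomes)
    counts: dict[str, int] = {br: 0 for br in tree.branches}

    s1, s2 = tree.cherry1
    s3, s4 = tree.cherry2
    _converge_cherry(genomes, tree.cherry1, [s3, s4], counts)
    x = genomes[s1]
    _converge_cherry(genomes, tree.cherry2, [s1], counts)
    y = genomes[s3]

    scen = sorting_scenario(x, target=y, policy="smallest_first")
    m = len(scen)
    kx = (m + 1) // 2
    cur = x
    for i, j in scen.steps[:kx]:
        cur = reverse_segment(cur, i, j)
    counts["cherry1"] += kx
    counts["cherry2"] += m - kx
    return SignedPermutation(cur), counts


def read_permutation_file(path) -> dict[tuple[str, str], SignedPermutation]:
    """Read '>species element' headers followed by whitespace-separated
    signed integers (possibly spanning lines)."""
    out: dict[tuple[str, str], SignedPermutation] = {}
    key, buf = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if key is not None:
                    out[key] = SignedPermutation(tuple(int(x) for x in buf))
                parts = line[1:].split()
                if len(parts) != 2:
                    raise ValidationError(f"bad permutation header: {line!r}")
                key, buf = (parts[0], parts[1]), []
            else:
                if key is None:
                    raise ValidationError("permutation data before any header")
                buf.extend(line.split())
    if key is not None:
        out[key] = SignedPermutation(tuple(int(x) for x in buf))
    return out


def write_permutation_file(perms: dict, path) -> None:
    with open(path, "w") as fh:
        for (species, element), p in perms.items():
            elems = p.elements if isinstance(p, SignedPermutation) else tuple(p)
            fh.write(f">{species} {element}\n")
            fh.write(" ".join(f"{x:+d}" for x in elems) + "\n")


def exhaustive_median(perms, max_n: int = 6) -> tuple[tuple[int, ...], int]:
    """Exact median order minimizing the summed reversal distance to the
    given permutations, by enumeration of the whole group (test oracle;
    n <= ``max_n``)."""
    tuples = [_as_tuple(p) for p in perms]
    n = len(tuples[0])
    if n > max_n:
        raise KaryoshuffleError(f"exhaustive median refuses n={n} > {max_n}")
    best, best_score = None, None
    for cand in all_signed_permutations(n):
        score = sum(inversion_distance(cand, t) for t in tuples)
        if best_score is None or score < best_score:
            best, best_score = cand, score
    return best, best_score
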
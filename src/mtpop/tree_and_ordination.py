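"""Distance-matrix phylogenetics and ordination for population Fst tables.

Covers the downstream half of a between-population mtDNA comparison:
parsing the customary combined matrix layout (pairwise Fst below the
diagonal, permutation p-values above, ``*`` on the diagonal, labels in an
accompanying numbered key), nearest/farthest queries, Neighbor-Joining tree
reconstruction (Saitou–Nei agglomeration with the Studier–Keppler
Q-criterion), and 2-D ordination of the Fst profiles.

Neighbor-Joining is implemented here rather than delegated: it is exact on
additive matrices (topology and branch lengths), deterministic under a
lexicographic tie-break, and clamps the occasional negative branch length a
non-additive Fst matrix produces to zero (with a logged warning).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass

import numpy as np

from .errors import NumericError, ParseError, ValidationError

logger = logging.getLogger("mtpop.tree")

# ---------------------------------------------------------------------------
# labelled matrices
# ---------------------------------------------------------------------------

def _check_labels(labels) -> tuple[str, ...]:
    labels = tuple(str(l) for l in labels)
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate matrix labels")
    return labels


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance (Fst) matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", _check_labels(self.labels))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.labels),) * 2:
            raise ValidationError("matrix shape does not match label count")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        object.__setattr__(self, "values", values)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown population {label!r}") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def floored(self) -> "DistanceMatrix":
        """Copy with negative entries floored at 0 (distance-export convention)."""
        return DistanceMatrix(self.labels, np.maximum(self.values, 0.0))

    def to_square_tsv(self, decimals: int = 5) -> str:
        lines = ["\t".join(("",) + self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append(
                lab + "\t" + "\t".join(f"{v:.{decimals}f}" for v in self.values[i])
            )
        return "\n".join(lines) + "\n"

    def to_phylip(self, decimals: int = 5) -> str:
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            name = lab.replace(" ", "_")
            lines.append(
                name + "\t" + "\t".join(f"{v:.{decimals}f}" for v in self.values[i])
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SignificanceMatrix:
    """Permutation p-values aligned to a DistanceMatrix's label order."""

    labels: tuple[str, ...]
    values: np.ndarray  # diagonal NaN

    def __post_init__(self):
        object.__setattr__(self, "labels", _check_labels(self.labels))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.labels),) * 2:
            raise ValidationError("matrix shape does not match label count")
        off = ~np.eye(len(self.labels), dtype=bool)
        if np.nanmax(values[off], initial=0.0) > 1.0 or np.nanmin(values[off], initial=0.0) < 0.0:
            raise ValidationError("p-values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def value(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# parsing the combined Fst / p-value dialect
# ---------------------------------------------------------------------------

def parse_fst_pvalue_table(text: str) -> tuple[DistanceMatrix, SignificanceMatrix]:
    """Parse the combined lower-Fst / upper-p dialect.

    Layout: optional ``#`` comment lines, one of which may carry the label
    key (``# key: 1, Xibe; 2, Guangdong Han; ...``); a header row; then one
    row per population with ``*`` on the diagonal.  Bold/emphasis markup
    (``**x**``, ``_x_``) is stripped.  Without a key, the header names are
    used as labels.
    """
    key: dict[int, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip("# \t")
            if body.lower().startswith("key:"):
                for entry in body[4:].split(";"):
                    entry = entry.strip()
                    if not entry:
                        continue
                    try:
                        num, name = entry.split(",", 1)
                        key[int(num.strip())] = name.strip()
                    except ValueError:
                        raise ParseError(f"bad key entry {entry!r}") from None
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = [c.strip() for c in cells]
        else:
            rows.append([c.strip() for c in cells])
    if header is None or not rows:
        raise ParseError("empty Fst/p-value table")
    k = len(rows)
    if any(len(r) != k + 1 for r in rows):
        raise ParseError(
            f"table is not square: {k} rows but row widths {[len(r) - 1 for r in rows]}"
        )
    ids = [r[0] for r in rows]
    if key:
        try:
            labels = tuple(key[int(i)] for i in ids)
        except (KeyError, ValueError) as exc:
            raise ParseError(f"row id missing from key: {exc}") from None
    else:
        labels = tuple(ids)
    fst = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    for i, row in enumerate(rows):
        for j, raw in enumerate(row[1:]):
            cell = raw.replace("**", "").replace("_", "").strip()
            if i == j:
                if cell != "*":
                    raise ParseError(f"row {i + 1}, col {j + 1}: expected '*' diagonal")
                continue
            try:
                val = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i + 1}, col {j + 1}: non-numeric cell {raw!r}"
                ) from None
            if i > j:  # lower triangle: Fst
                fst[i, j] = fst[j, i] = val
            else:  # upper triangle: p-value
                pval[i, j] = pval[j, i] = val
    return DistanceMatrix(labels, fst), SignificanceMatrix(labels, pval)


def write_fst_pvalue_table(
    dm: DistanceMatrix, sm: SignificanceMatrix, decimals: int = 5
) -> str:
    """Serialize back to the combined dialect (numeric cells reproduced)."""
    if dm.labels != sm.labels:
        raise ValidationError("Fst and p matrices carry different label orders")
    k = len(dm.labels)
    lines = [
        "# key: " + "; ".join(f"{i + 1}, {lab}" for i, lab in enumerate(dm.labels)),
        "\t".join(["Populations"] + [str(i + 1) for i in range(k)]),
    ]
    for i in range(k):
        cells = [str(i + 1)]
        for j in range(k):
            if i == j:
                cells.append("*")
            elif i > j:
                cells.append(f"{dm.values[i, j]:.{decimals}f}")
            else:
                cells.append(f"{sm.values[i, j]:.{decimals}f}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def parse_square_tsv(text: str) -> DistanceMatrix:
    """Read a labelled square TSV (header row + label column)."""
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if len(lines) < 2:
        raise ParseError("empty square distance table")
    header = lines[0].split("\t")[1:]
    labels, values = [], []
    for line in lines[1:]:
        cells = line.split("\t")
        labels.append(cells[0])
        try:
            values.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in row {cells[0]!r}: {exc}") from None
    if [h.strip() for h in header] != [l.strip() for l in labels]:
        raise ParseError("square table header and row labels disagree")
    return DistanceMatrix(tuple(labels), np.array(values))


def parse_phylip(text: str) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (count line + label rows)."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ParseError("empty PHYLIP matrix")
    try:
        k = int(lines[0].split()[0])
    except ValueError:
        raise ParseError("PHYLIP matrix must start with the taxon count") from None
    if len(lines) != k + 1:
        raise ParseError(f"PHYLIP matrix announces {k} taxa but has {len(lines) - 1} rows")
    labels, values = [], []
    for line in lines[1:]:
        parts = line.split()
        labels.append(parts[0])  # PHYLIP names are kept verbatim
        try:
            values.append([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in row {parts[0]!r}: {exc}") from None
    return DistanceMatrix(tuple(labels), np.array(values))


def read_distance_matrix(text: str, dialect: str = "auto") -> DistanceMatrix:
    """Dispatch across the three supported input dialects."""
    if dialect == "auto":
        stripped = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
        first = stripped[0].split("\t") if stripped else []
        if stripped and stripped[0].split()[0].isdigit() and len(first) <= 1:
            dialect = "phylip"
        elif any("*" in l for l in stripped[1:2]) or (
            len(stripped) > 1 and "*" in stripped[1]
        ):
            dialect = "table"
        else:
            dialect = "square"
    if dialect == "table":
        return parse_fst_pvalue_table(text)[0]
    if dialect == "square":
        return parse_square_tsv(text)
    if dialect == "phylip":
        return parse_phylip(text)
    raise ParseError(f"unknown distance-matrix dialect {dialect!r}")


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def nearest_and_farthest(
    m: DistanceMatrix, focal: str
) -> tuple[tuple[str, float], tuple[str, float]]:
    """Closest and most distant populations to ``focal`` (off-diagonal row
    argmin/argmax; ties broken by label order)."""
    if len(m.labels) < 2:
        raise ValidationError("need at least two populations")
    i = m.index(focal)
    best_lo = best_hi = None
    for j, lab in enumerate(m.labels):
        if j == i:
            continue
        v = float(m.values[i, j])
        if best_lo is None or v < best_lo[1]:
            best_lo = (lab, v)
        if best_hi is None or v > best_hi[1]:
            best_hi = (lab, v)
    return best_lo, best_hi


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Unrooted tree with branch lengths, as an edge-weighted adjacency map.

    Leaves are the original labels (strings); internal nodes are integers.
    """

    adjacency: dict  # node -> dict[node, float]

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adjacency if isinstance(n, str))

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each canonicalised as the side not
        containing the lexicographically smallest leaf."""
        ref = min(self.leaves)
        out = set()
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                if isinstance(a, str) or isinstance(b, str):
                    continue  # pendant edges are trivial
                side = self._leaves_beyond(a, b)
                if ref in side:
                    side = set(self.leaves) - side
                if 1 < len(side) < len(self.leaves) - 1:
                    out.add(frozenset(side))
        return out

    def has_split(self, group) -> bool:
        """True if some edge separates exactly ``group`` from the rest."""
        group = set(group)
        other = set(self.leaves) - group
        canon = group if min(self.leaves) not in group else other
        return frozenset(canon) in self.splits()

    def _leaves_beyond(self, frm, to) -> set:
        """Leaves on ``to``'s side of the (frm, to) edge."""
        seen, stack, out = {frm, to}, [to], set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.add(node)
            for nxt in self.adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return out

    def patristic(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix."""
        leaves = self.leaves
        idx = {l: i for i, l in enumerate(leaves)}
        values = np.zeros((len(leaves),) * 2)
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nxt, w in self.adjacency[node].items():
                    if nxt not in dist:
                        dist[nxt] = dist[node] + w
                        stack.append(nxt)
            for dst in leaves:
                values[idx[src], idx[dst]] = dist[dst]
        return DistanceMatrix(tuple(leaves), values)

    def to_newick(self, decimals: int = 10) -> str:
        """Newick string rooted at an internal node (or the first leaf for
        2-taxon trees); labels with spaces are quoted."""
        internal = [n for n in self.adjacency if not isinstance(n, str)]
        root = internal[-1] if internal else self.leaves[0]

        def fmt(label: str) -> str:
            return f"'{label}'" if re.search(r"[\s(),:;]", label) else label

        def rec(node, parent) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                return fmt(node)
            inner = ",".join(
                f"{rec(c, node)}:{self.adjacency[node][c]:.{decimals}g}"
                for c in children
            )
            return f"({inner})"

        return rec(root, None) + ";"


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Neighbor-Joining (Saitou–Nei) from a labelled distance matrix.

    Agglomerates the pair minimising the Studier–Keppler criterion
    Q(i,j) = (r-2) d(i,j) - R_i - R_j; ties go to the lexicographically
    smallest label pair (cluster label = smallest member leaf), making the
    output deterministic.  Exact on additive matrices; negative branch
    lengths are clamped to zero with a logged warning.
    """
    if len(m.labels) < 3:
        raise NumericError("Neighbor-Joining requires at least 3 taxa")
    # cluster ids: leaf labels; internal nodes get integers
    dist: dict[tuple, float] = {}
    nodes: list = list(m.labels)
    sort_key = {lab: (lab,) for lab in nodes}  # lexicographic cluster identity
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            dist[frozenset((a, nodes[j]))] = float(m.values[i, j])
    adjacency: dict = {n: {} for n in nodes}
    next_id = 0

    def d(a, b) -> float:
        return dist[frozenset((a, b))]

    def clamp(v: float, a, b) -> float:
        if v < 0:
            logger.warning("negative branch length %.6g on edge %s-%s clamped to 0", v, a, b)
            return 0.0
        return v

    def connect(a, b, length) -> None:
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    while len(nodes) > 3:
        r = len(nodes)
        R = {a: sum(d(a, b) for b in nodes if b != a) for a in nodes}
        best = None
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                q = (r - 2) * d(a, b) - R[a] - R[b]
                pair_key = tuple(sorted((sort_key[a], sort_key[b])))
                if best is None or (q, pair_key) < (best[0], best[1]):
                    best = (q, pair_key, a, b)
        _, _, a, b = best
        va = d(a, b) / 2 + (R[a] - R[b]) / (2 * (r - 2))
        vb = d(a, b) - va
        u = next_id
        next_id += 1
        connect(a, u, clamp(va, a, u))
        connect(b, u, clamp(vb, b, u))
        for c in nodes:
            if c in (a, b):
                continue
            dist[frozenset((u, c))] = (d(a, c) + d(b, c) - d(a, b)) / 2
        nodes = [c for c in nodes if c not in (a, b)] + [u]
        sort_key[u] = min(sort_key[a], sort_key[b])
    a, b, c = nodes
    u = next_id
    connect(a, u, clamp((d(a, b) + d(a, c) - d(b, c)) / 2, a, u))
    connect(b, u, clamp((d(a, b) + d(b, c) - d(a, c)) / 2, b, u))
    connect(c, u, clamp((d(a, c) + d(b, c) - d(a, b)) / 2, c, u))
    return Tree(adjacency)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """2-D (or k-D) coordinates per population plus explained fractions,
    axes ordered by decreasing explained variance."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n_labels, k)
    explained_fraction: np.ndarray  # (k,)

    def coordinate(self, label: str) -> np.ndarray:
        return self.coordinates[self.labels.index(label)]

    def to_tsv(self) -> str:
        k = self.coordinates.shape[1]
        header = ["population"] + [f"axis{i + 1}" for i in range(k)]
        lines = ["\t".join(header)]
        lines.append(
            "\t".join(
                ["#explained_fraction"] + [f"{v:.6f}" for v in self.explained_fraction]
            )
        )
        for i, lab in enumerate(self.labels):
            lines.append(
                lab + "\t" + "\t".join(f"{v:.6f}" for v in self.coordinates[i])
            )
        return "\n".join(lines) + "\n"


def ordinate(m: DistanceMatrix, k: int = 2, method: str = "pca") -> OrdinationResult:
    """Low-dimensional ordination of populations from their Fst matrix.

    ``method="pca"`` (default) treats each population's row of pairwise Fst
    values as its feature profile and extracts principal components of the
    centred profiles.  ``method="mds"`` is classical metric MDS / principal
    coordinates (Torgerson double-centering of squared distances).  Axes are
    ordered by explained fraction; per-axis sign is fixed so the
    largest-magnitude loading (PCA) or coordinate (MDS) is positive;
    coordinates are centred (mean zero per axis).
    """
    npop = len(m.labels)
    if not 0 < k < npop:
        raise NumericError(f"need 0 < k < {npop} ordination axes, got {k}")
    X = m.values
    if method == "pca":
        Xc = X - X.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        coords = Xc @ Vt[:k].T
        with np.errstate(invalid="ignore", divide="ignore"):
            total = float((S**2).sum())
        explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
        for axis in range(k):
            lead = np.argmax(np.abs(Vt[axis]))
            if Vt[axis, lead] < 0:
                coords[:, axis] *= -1
    elif method == "mds":
        D2 = X**2
        J = np.eye(npop) - np.ones((npop, npop)) / npop
        B = -0.5 * J @ D2 @ J
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        pos = np.maximum(eigval, 0.0)
        coords = eigvec[:, :k] * np.sqrt(pos[:k])
        total = float(pos.sum())
        explained = pos[:k] / total if total > 0 else np.zeros(k)
        for axis in range(k):
            lead = np.argmax(np.abs(coords[:, axis]))
            if coords[lead, axis] < 0:
                coords[:, axis] *= -1
    else:
        raise ValidationError(f"unknown ordination method {method!r}")
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(m.labels, coords, np.asarray(explained))
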
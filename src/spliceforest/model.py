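"""Core domain types for transcript-phylogeny reconstruction.

The model is two-level: a rooted binary *gene tree* carries the evolution of
the gene structure (each orthologous exon column is absent, alternative or
constitutive in each gene), while *transcripts* — subsets of the gene's exons,
encoded as integer vectors over exon columns — evolve on top of it.  Gene-level
events are free; transcript-level events (birth, death, exon gain/loss) carry
the costs in :class:`Costs`.

Alternative 3'/5' splice sites are encoded as a single column whose alphabet
has more than one included configuration (``{0, 1, ..., m}``); intron retention
is encoded as an extra cassette-exon column.  Paralogous exons must be given
distinct columns by the caller; ortholog grouping is out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "ExonState",
    "GeneTree",
    "ExonColumn",
    "Transcript",
    "Costs",
    "ExonStateMatrix",
    "Instance",
    "InputError",
    "ValidationError",
    "read_instance",
    "write_instance",
]


class InputError(ValueError):
    """Malformed or inconsistent input files (I/O level)."""


class ValidationError(ValueError):
    """Input parses but violates a model invariant."""


class ExonState(enum.Enum):
    """Gene-level status of one exon column in one gene."""

    ABSENT = "0"
    ALTERNATIVE = "1A"
    CONSTITUTIVE = "1C"

    @property
    def present(self) -> bool:
        return self is not ExonState.ABSENT

    @property
    def order(self) -> int:
        # deterministic enumeration order ABSENT < ALTERNATIVE < CONSTITUTIVE
        return ("0", "1A", "1C").index(self.value)


class GeneTree:
    """A rooted binary gene tree with uniquely named nodes.

    Multifurcating trees are rejected: the leaf-assignment recurrence assumes
    exactly two children per internal node.
    """

    def __init__(self, root: str, children: dict[str, tuple[str, str]]):
        self.root = root
        self._children = dict(children)
        self._parent: dict[str, str] = {}
        for p, (l, r) in self._children.items():
            self._parent[l] = p
            self._parent[r] = p
        self._check()
        self._postorder = tuple(self._compute_postorder(root))
        self.leaves = tuple(n for n in self._postorder if self.is_leaf(n))
        self._leafset: dict[str, frozenset[str]] = {}
        for n in self._postorder:
            if self.is_leaf(n):
                self._leafset[n] = frozenset((n,))
            else:
                l, r = self._children[n]
                self._leafset[n] = self._leafset[l] | self._leafset[r]
        self._depth: dict[str, int] = {root: 0}
        for n in reversed(self._postorder):
            for c in self.children(n):
                self._depth[c] = self._depth[n] + 1

    def _check(self) -> None:
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise InputError(f"duplicate node name {n!r} in gene tree")
            seen.add(n)
            stack.extend(self._children.get(n, ()))
        extra = set(self._children) - seen
        if extra:
            raise InputError(f"unreachable internal nodes: {sorted(extra)}")
        if self.root in self._parent:
            raise InputError("root has a parent")

    def _compute_postorder(self, node: str):
        for c in self._children.get(node, ()):
            yield from self._compute_postorder(c)
        yield node

    # -- queries ---------------------------------------------------------
    def is_leaf(self, node: str) -> bool:
        return node not in self._children

    def children(self, node: str) -> tuple[str, ...]:
        return self._children.get(node, ())

    def parent(self, node: str) -> str | None:
        return self._parent.get(node)

    def postorder(self) -> tuple[str, ...]:
        return self._postorder

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._postorder

    def leaf_set(self, node: str) -> frozenset[str]:
        """Leaves of the gene subtree rooted at ``node``."""
        return self._leafset[node]

    def depth(self, node: str) -> int:
        return self._depth[node]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for p in self._postorder for c in self.children(p)]

    def ancestors(self, node: str) -> list[str]:
        """Path ``node, parent(node), ..., root`` (inclusive)."""
        out = [node]
        while (p := self._parent.get(out[-1])) is not None:
            out.append(p)
        return out

    def lca(self, names) -> str:
        paths = [set(self.ancestors(n)) for n in names]
        common = set.intersection(*paths)
        # deepest common ancestor
        return max(common, key=self._depth.__getitem__)

    def __contains__(self, node: str) -> bool:
        return node in self._leafset

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneTree)
            and self.root == other.root
            and self._children == other._children
        )

    def __hash__(self):  # pragma: no cover - trees are rarely hashed
        return hash((self.root, tuple(sorted(self._children.items()))))

    # -- Newick I/O ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path) -> "GeneTree":
        text = Path(source).read_text() if isinstance(source, Path) else str(source)
        if "(" not in text and Path(str(source)).exists():
            text = Path(str(source)).read_text()
        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise InputError(f"cannot parse Newick: {exc}") from exc
        counter = 0
        names: dict[int, str] = {}
        taken = set()
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label:
                if label in taken:
                    raise InputError(f"duplicate node name {label!r}")
                taken.add(label)
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                counter += 1
                label = f"n{counter}"
                while label in taken:
                    counter += 1
                    label = f"n{counter}"
                taken.add(label)
            names[id(nd)] = label
        children: dict[str, tuple[str, str]] = {}
        for nd in dt.preorder_node_iter():
            kids = nd.child_nodes()
            if len(kids) == 0:
                continue
            if len(kids) != 2:
                raise InputError(
                    f"gene tree must be binary; node {names[id(nd)]!r} has "
                    f"{len(kids)} children"
                )
            children[names[id(nd)]] = (names[id(kids[0])], names[id(kids[1])])
        if not children:
            raise InputError("gene tree must have at least two leaves")
        return cls(names[id(dt.seed_node)], children)

    def to_newick(self) -> str:
        def fmt(n: str) -> str:
            if self.is_leaf(n):
                return n
            l, r = self._children[n]
            return f"({fmt(l)},{fmt(r)}){n}"

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class ExonColumn:
    """One orthologous exon column.

    ``n_states`` is the number of *included* configurations m: a transcript
    value lies in ``{0, 1, ..., m}`` where 0 means the exon is excluded.
    Ordinary cassette/constitutive exons have m = 1; alternative 3'/5'-site
    exons use m > 1, one value per site configuration.
    """

    id: str
    n_states: int = 1

    def __post_init__(self):
        if self.n_states < 1:
            raise ValidationError(f"column {self.id!r}: n_states must be >= 1")

    @property
    def alphabet(self) -> range:
        return range(self.n_states + 1)


@dataclass(frozen=True)
class Transcript:
    """An observed transcript: integer vector over the exon columns."""

    id: str
    gene: str
    values: tuple[int, ...]


@dataclass(frozen=True)
class Costs:
    """Event costs of the transcript level.

    birth: cost c_B of creating a transcript tree; death: cost c_D of a
    transcript loss; exon: cost c_E of one transcript-level exon gain/loss
    (``math.inf`` forbids transcript-level flips).  Gene-level events are free:
    on an edge where an exon was gained as constitutive or lost at the gene
    level, the corresponding column change costs nothing.
    """

    birth: float = 1.0
    death: float = 1.0
    exon: float = 1.0

    def __post_init__(self):
        for name in ("birth", "death", "exon"):
            if getattr(self, name) < 0:
                raise ValidationError(f"cost {name} must be non-negative")


class ExonStateMatrix:
    """Per-gene-node vector of :class:`ExonState` over all exon columns."""

    def __init__(self, states: dict[str, tuple[ExonState, ...]]):
        self._states = dict(states)
        lengths = {len(v) for v in self._states.values()}
        if len(lengths) > 1:
            raise ValidationError("rows of an ExonStateMatrix differ in length")

    def __getitem__(self, node: str) -> tuple[ExonState, ...]:
        return self._states[node]

    def __contains__(self, node: str) -> bool:
        return node in self._states

    def nodes(self):
        return self._states.keys()

    def n_columns(self) -> int:
        return len(next(iter(self._states.values()))) if self._states else 0

    def __eq__(self, other):
        return isinstance(other, ExonStateMatrix) and self._states == other._states

    def gain_counts(self, tree: GeneTree) -> list[int]:
        """Per column: number of ABSENT→present origins (root presence counts)."""
        ncol = self.n_columns()
        gains = [0] * ncol
        for i in range(ncol):
            if self[tree.root][i].present:
                gains[i] += 1
            for p, c in tree.edges():
                if not self[p][i].present and self[c][i].present:
                    gains[i] += 1
        return gains

    def is_dollo(self, tree: GeneTree) -> bool:
        """True iff every column has at most one origin over the whole tree."""
        return all(g <= 1 for g in self.gain_counts(tree))

    # -- TSV dump --------------------------------------------------------
    def to_tsv(self, columns: list[ExonColumn]) -> str:
        lines = ["gene\t" + "\t".join(c.id for c in columns)]
        for node in sorted(self._states):
            lines.append(
                node + "\t" + "\t".join(s.value for s in self._states[node])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ExonStateMatrix":
        rows = [ln.split("\t") for ln in text.strip().splitlines()]
        states = {
            r[0]: tuple(ExonState(tok) for tok in r[1:]) for r in rows[1:]
        }
        return cls(states)


@dataclass
class Instance:
    """A validated problem instance: gene tree, per-leaf transcripts, columns."""

    tree: GeneTree
    transcripts: dict[str, list[Transcript]]
    columns: list[ExonColumn] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        leafset = set(self.tree.leaves)
        for gene, ts in self.transcripts.items():
            if gene not in leafset:
                raise InputError(
                    f"transcript matrix references gene {gene!r} absent from "
                    "the gene tree leaves"
                )
            for t in ts:
                if len(t.values) != len(self.columns):
                    raise ValidationError(
                        f"transcript {t.id!r}: {len(t.values)} values for "
                        f"{len(self.columns)} columns"
                    )
                for col, v in zip(self.columns, t.values):
                    if v not in col.alphabet:
                        raise ValidationError(
                            f"transcript {t.id!r}: value {v} outside alphabet "
                            f"of column {col.id!r} (0..{col.n_states})"
                        )

    def leaf_counts(self) -> dict[str, int]:
        return {g: len(self.transcripts.get(g, [])) for g in self.tree.leaves}


def _parse_column_header(token: str) -> ExonColumn:
    if ":" in token:
        name, m = token.rsplit(":", 1)
        try:
            return ExonColumn(name, int(m))
        except ValueError as exc:
            raise InputError(f"bad column header {token!r}") from exc
    return ExonColumn(token, 1)


def read_instance(gene_tree_path: str | Path, transcript_matrix_path: str | Path) -> Instance:
    """Read a Newick gene tree and a TSV transcript matrix.

    The matrix has a header row ``transcript_id  gene_id  <col>[:m] ...`` and
    one row per transcript; column alphabets default to {0,1} and can be
    widened by a ``:m`` suffix in the header.
    """
    tree = GeneTree.from_newick(Path(gene_tree_path))
    try:
        df = pd.read_csv(transcript_matrix_path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InputError(f"cannot parse transcript matrix: {exc}") from exc
    if list(df.columns[:2]) != ["transcript_id", "gene_id"]:
        raise InputError(
            "transcript matrix must start with columns transcript_id, gene_id"
        )
    declared = [_parse_column_header(c) for c in df.columns[2:]]
    observed_max = {c.id: 0 for c in declared}
    records: dict[str, list[Transcript]] = {}
    for _, row in df.iterrows():
        try:
            values = tuple(int(row[c]) for c in df.columns[2:])
        except ValueError as exc:
            raise InputError(f"non-integer transcript value: {exc}") from exc
        if any(v < 0 for v in values):
            raise ValidationError("transcript values must be non-negative")
        for col, v in zip(declared, values):
            observed_max[col.id] = max(observed_max[col.id], v)
        t = Transcript(str(row["transcript_id"]), str(row["gene_id"]), values)
        records.setdefault(t.gene, []).append(t)
    # widen undeclared alphabets to what the data uses
    columns = [
        col if ":" in token else ExonColumn(col.id, max(observed_max[col.id], 1))
        for token, col in zip(df.columns[2:], declared)
    ]
    for g in tree.leaves:
        records.setdefault(g, [])
    return Instance(tree, records, columns)


def write_instance(instance: Instance, gene_tree_path: str | Path,
                   transcript_matrix_path: str | Path) -> None:
    Path(gene_tree_path).write_text(instance.tree.to_newick() + "\n")
    header = ["transcript_id", "gene_id"] + [
        c.id if c.n_states == 1 else f"{c.id}:{c.n_states}"
        for c in instance.columns
    ]
    lines = ["\t".join(header)]
    for gene in instance.tree.leaves:
        for t in instance.transcripts.get(gene, []):
            lines.append("\t".join([t.id, t.gene] + [str(v) for v in t.values]))
    Path(transcript_matrix_path).write_text("\n".join(lines) + "\n")
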
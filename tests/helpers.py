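"""Independent oracles used across the test suite.

Everything here is deliberately written without touching the production
algorithms it checks: the normalization oracle works by exhaustive
enumeration of haplotype-equivalent representations, and the scheme oracle
evaluates structural rule descriptions directly in Python.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from varan.variants import ReferenceSequence, Variant


def apply_whole_contig(v: Variant, ref: ReferenceSequence) -> str:
    """Edited full-contig sequence (the alternate haplotype)."""
    seq = ref.contigs[v.chrom]
    off = v.pos - 1
    assert seq[off : off + len(v.ref)] == v.ref
    return seq[:off] + v.alt + seq[off + len(v.ref) :]


def enumerate_equivalents(v: Variant, ref: ReferenceSequence) -> list[Variant]:
    """Every (pos, ref, alt) whose application to the contig yields the
    same alternate haplotype.  Feasible because test contigs are short."""
    seq = ref.contigs[v.chrom]
    target = apply_whole_contig(v, ref)
    n, m = len(seq), len(target)
    out = []
    for pos in range(1, n + 1):
        for rlen in range(1, n - pos + 2):
            # alt is forced: target = seq[:pos-1] + alt + seq[pos-1+rlen:]
            suffix_len = n - (pos - 1) - rlen
            alt = target[pos - 1 : m - suffix_len]
            if not alt or alt == seq[pos - 1 : pos - 1 + rlen]:
                continue
            if target[: pos - 1] != seq[: pos - 1]:
                continue
            if suffix_len and target[m - suffix_len :] != seq[n - suffix_len :]:
                continue
            cand = Variant(v.chrom, pos, seq[pos - 1 : pos - 1 + rlen], alt)
            if apply_whole_contig(cand, ref) == target:
                out.append(cand)
    return out


def oracle_normalize(v: Variant, ref: ReferenceSequence) -> Variant:
    """Unique parsimonious leftmost equivalent, by brute force: minimal
    total allele length, then minimal position."""
    cands = enumerate_equivalents(v, ref)
    best_len = min(len(c.ref) + len(c.alt) for c in cands)
    minimal = [c for c in cands if len(c.ref) + len(c.alt) == best_len]
    minimal.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return minimal[0]


# ---------------------------------------------------------------------------
# structural scheme oracle
# ---------------------------------------------------------------------------


@dataclass
class Leaf:
    """One structural predicate, renderable to expression text."""

    kind: str  # "cmp" | "empty" | "contains" | "th_cmp"
    column: str
    op: str = "<"
    value: object = None
    threshold: str = ""

    def render(self) -> str:
        if self.kind == "empty":
            return f'isEmpty(x("{self.column}"))'
        if self.kind == "contains":
            return f'stringContains(x("{self.column}"), "{self.value}")'
        if self.kind == "th_cmp":
            return f'x("{self.column}") {self.op} th("{self.threshold}")'
        if isinstance(self.value, str):
            return f'x("{self.column}") {self.op} "{self.value}"'
        return f'x("{self.column}") {self.op} {self.value}'

    def evaluate(self, row: dict, thresholds: dict) -> bool:
        raw = str(row.get(self.column, ""))
        if self.kind == "empty":
            return raw == ""
        if self.kind == "contains":
            return str(self.value) in raw
        if self.kind in ("cmp", "th_cmp"):
            rhs = thresholds[self.threshold] if self.kind == "th_cmp" else self.value

            def as_num(x):
                try:
                    return float(str(x))
                except ValueError:
                    return None

            ln, rn = as_num(raw), as_num(rhs)
            if self.op in ("==", "!="):
                if ln is not None and rn is not None:
                    equal = ln == rn
                else:
                    equal = raw == str(rhs)
                return equal if self.op == "==" else not equal
            if ln is None or rn is None:
                return False
            return {
                "<": ln < rn,
                "<=": ln <= rn,
                ">": ln > rn,
                ">=": ln >= rn,
            }[self.op]
        raise AssertionError(self.kind)


@dataclass
class Tree:
    op: str | None  # "AND"/"OR"/None
    leaves: list = field(default_factory=list)  # Leaf or Tree

    def render(self) -> dict:
        if self.op is None:
            return {"expr": self.leaves[0].render()}
        return {"op": self.op, "children": [c.render() for c in self.leaves]}

    def evaluate(self, row: dict, thresholds: dict) -> bool:
        if self.op is None:
            return self.leaves[0].evaluate(row, thresholds)
        results = [c.evaluate(row, thresholds) for c in self.leaves]
        return all(results) if self.op == "AND" else any(results)


@dataclass
class StructuralEntry:
    id: str
    tree: Tree
    artifact_weight: float
    polymorphism_weight: float
    active: bool = True


def render_scheme(
    entries: list[StructuralEntry], thresholds: dict[str, float]
) -> dict:
    return {
        "name": "generated",
        "version": "t",
        "categories": [
            {
                "name": "generated",
                "entries": [
                    {
                        "id": e.id,
                        "label": e.id,
                        "active": e.active,
                        "artifact_weight": e.artifact_weight,
                        "polymorphism_weight": e.polymorphism_weight,
                        "condition": e.tree.render(),
                    }
                    for e in entries
                ],
            }
        ],
        "thresholds": {
            name: {"default": val, "min": val - 100, "max": val + 100}
            for name, val in thresholds.items()
        },
        "cutoffs": {"artifact_cutoff": 1.0, "polymorphism_cutoff": 1.0},
    }


def oracle_scores(
    entries: list[StructuralEntry], row: dict, thresholds: dict[str, float]
) -> tuple[float, float]:
    a = p = 0.0
    for e in entries:
        if e.active and e.tree.evaluate(row, thresholds):
            a += e.artifact_weight
            p += e.polymorphism_weight
    return a, p
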
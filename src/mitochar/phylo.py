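"""Post-hoc interrogation of published phylogenies: genus monophyly.

A genus with two or more tips is called monophyletic on an unrooted tree
exactly when some edge's removal bisects the leaf set into that genus's
tips versus everything else (the bipartition criterion). This is robust to
where the tree happens to be rooted, which matters when auditing published
figures whose rooting is an editorial choice. Singleton genera are labelled
``trivial``; a genus spanning all tips is monophyletic by definition.

Trees are handled through dendropy; tip-to-genus maps come either from a
two-column TSV or from a regex applied to tip labels (default: the token
before the first underscore, the common ``Genus_species_accession``
labelling scheme).
"""

from __future__ import annotations

import re

import dendropy

from mitochar.errors import ComputeError, FormatError

DEFAULT_GENUS_REGEX = r"^([^_\s]+)"

MONOPHYLETIC = "monophyletic"
NON_MONOPHYLETIC = "non-monophyletic"
TRIVIAL = "trivial"


class GenusTree:
    """A leaf-labelled tree plus a tip → genus mapping.

    Parameters
    ----------
    tree : dendropy.Tree
        Topology with unique tip labels; branch lengths and support values
        are retained but unused by the monophyly test.
    genus_map : dict
        Tip label → genus. Must cover every tip unless the tip is listed in
        ``ignore``.
    ignore : set of str, optional
        Tip labels (e.g. an outgroup) to leave out of all verdicts.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        genus_map: dict[str, str],
        ignore: set[str] | None = None,
    ) -> None:
        self.tree = tree
        self.ignore = set(ignore or ())
        labels = [t.label for t in tree.taxon_namespace]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise FormatError(f"duplicate tip labels: {dupes}")
        unmapped = [x for x in labels if x not in genus_map and x not in self.ignore]
        if unmapped:
            raise FormatError(
                f"{len(unmapped)} tip(s) missing from the genus map "
                f"(e.g. {unmapped[:3]}); map them or pass ignore="
            )
        self.genus_map = {k: v for k, v in genus_map.items() if k not in self.ignore}

    @property
    def tips(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]

    def genera(self) -> dict[str, set[str]]:
        """Genus → set of tip labels (ignored tips excluded)."""
        out: dict[str, set[str]] = {}
        for tip in self.tips:
            if tip in self.ignore:
                continue
            out.setdefault(self.genus_map[tip], set()).add(tip)
        return out


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; internal node labels (supports) are tolerated."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"unparseable newick: {exc}") from exc
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in newick")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def read_genus_map(path) -> dict[str, str]:
    """Read a two-column (tip, genus) TSV; a header line is optional."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln_no}: expected two tab-separated columns")
            if ln_no == 1 and parts[0].lower() in ("tip", "label", "taxon"):
                continue
            out[parts[0].strip()] = parts[1].strip()
    return out


def genus_map_from_labels(
    labels: list[str], pattern: str = DEFAULT_GENUS_REGEX
) -> dict[str, str]:
    """Derive a tip → genus map by applying ``pattern`` to each tip label."""
    rx = re.compile(pattern)
    out: dict[str, str] = {}
    for label in labels:
        m = rx.search(label)
        if not m or not m.group(1):
            raise FormatError(f"genus regex {pattern!r} does not match tip {label!r}")
        out[label] = m.group(1)
    return out


def _leafset_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """All nontrivial leaf-set bipartition sides of the unrooted tree.

    Each edge contributes the set of tip labels on its child side; the
    complement side is checked by the caller. Trivial sides (single tips,
    all tips) are included — harmless, since queries are genera with >= 2
    and < all tips.
    """
    sides: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset({node.taxon.label})
        else:
            acc: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = acc
        sides.add(below[id(node)])
    return sides


def is_monophyletic(tree: dendropy.Tree, tipset: set[str]) -> bool:
    """Unrooted bipartition test for one tip set (>= 2 tips)."""
    all_tips = {t.label for t in tree.taxon_namespace}
    if not tipset <= all_tips:
        raise ComputeError(f"tips not in tree: {sorted(tipset - all_tips)}")
    if tipset == all_tips:
        return True
    target = frozenset(tipset)
    complement = frozenset(all_tips - tipset)
    sides = _leafset_bipartitions(tree)
    return target in sides or complement in sides


def monophyly_report(gtree: GenusTree) -> dict[str, str]:
    """Per-genus verdict: monophyletic, non-monophyletic, or trivial.

    Singleton genera are trivial (any single tip is vacuously a clade);
    other genera use the unrooted bipartition criterion. Ignored tips take
    no part, and a genus with zero mapped tips raises.
    """
    genera = gtree.genera()
    if not genera:
        raise ComputeError("no genera mapped")
    sides = _leafset_bipartitions(gtree.tree)
    considered = {tip for tips in genera.values() for tip in tips}
    report: dict[str, str] = {}
    for genus, tips in sorted(genera.items()):
        if not tips:
            raise ComputeError(f"genus {genus!r} has no mapped tips")
        if len(tips) == 1:
            report[genus] = TRIVIAL
        elif tips == considered:
            report[genus] = MONOPHYLETIC
        else:
            target = frozenset(tips)
            # ignored tips (e.g. outgroups) may sit inside a side; compare
            # on the considered tips only
            ok = any(
                (side & considered) in (target, frozenset(considered - target))
                for side in sides
            )
            report[genus] = MONOPHYLETIC if ok else NON_MONOPHYLETIC
    return report


def report_tsv(report: dict[str, str]) -> str:
    lines = ["genus\tverdict"]
    lines += [f"{g}\t{v}" for g, v in sorted(report.items())]
    return "\n".join(lines) + "\n"
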
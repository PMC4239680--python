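"""Readers and writers for genomes, trees, assignments and event logs.

Formats are plain text throughout: genomes as one line per genome
(``<id><TAB><tok1> <tok2> ...``, a leading ``-`` on a token marking negative
orientation), trees as newick (internal labels allowed, branch lengths
ignored — the model is event-count based), tabular outputs as TSV so gene
tokens never need quoting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import yaml

from .model import GeneOrder, History, Operation
from .tree import AssignedTree, RoundLog, TreeNode

log = logging.getLogger("orderalign")

EVENT_COLUMNS = ["branch_id", "kind", "length", "source_genome",
                 "source_start", "source_end", "target_genome", "target_start"]


@dataclass
class RunConfig:
    """Serializable run configuration; a run is reproducible from its
    config plus its inputs."""

    costs: str = "unit"          # "unit" | "dup_singleloss"
    model: str = "dup_singleloss"
    tie_break: str = "default"
    max_rounds: int = 20
    seed: int = 0
    out_dir: str = "."
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


def parse_genomes(path: str | Path) -> dict[str, GeneOrder]:
    """Read a genome file into a mapping id -> gene order."""
    out: dict[str, GeneOrder] = {}
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty genome file: {path}")
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" in line:
            gid, rest = line.split("\t", 1)
        else:  # tolerate space-separated ids
            parts = line.split(None, 1)
            gid, rest = parts[0], parts[1] if len(parts) > 1 else ""
        gid = gid.strip()
        if gid in out:
            raise ValueError(f"duplicate genome id {gid!r} on line {ln}")
        try:
            out[gid] = GeneOrder.from_tokens(rest.split(), id=gid)
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}") from exc
    return out


def write_genomes(genomes: dict[str, GeneOrder], path: str | Path) -> None:
    lines = [f"{gid}\t{' '.join(g.tokens())}" for gid, g in genomes.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def parse_tree(path_or_text: str | Path) -> AssignedTree:
    """Parse a rooted binary newick tree; leaf labels name the genomes."""
    text = str(path_or_text)
    if not text.lstrip().startswith("("):
        text = Path(path_or_text).read_text()
    dt = dendropy.Tree.get(data=text, schema="newick")
    counter = [0]

    def convert(dn) -> TreeNode:
        label = (dn.taxon.label if dn.taxon is not None else dn.label)
        if label:
            label = label.replace(" ", "_")
        if not label:
            counter[0] += 1
            label = f"N{counter[0]}"
        node = TreeNode(label)
        node.children = [convert(c) for c in dn.child_nodes()]
        return node

    root = convert(dt.seed_node)
    return AssignedTree(root)  # raises on non-binary nodes


def write_newick(tree: AssignedTree, path: Optional[str | Path] = None) -> str:
    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            return node.id
        return "(" + ",".join(rec(c) for c in node.children) + ")" + node.id

    text = rec(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_assignments(tree: AssignedTree, path: str | Path) -> None:
    rows = ["id\tgenes"]
    for nid, node in sorted(tree.nodes.items()):
        rows.append(f"{nid}\t{' '.join(node.genome.tokens())}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_assignments(path: str | Path) -> dict[str, GeneOrder]:
    out = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        gid, _, rest = line.partition("\t")
        out[gid] = GeneOrder.from_tokens(rest.split(), id=gid)
    return out


def write_events(histories: dict[str, History], path: str | Path) -> None:
    """Event-log TSV: one row per operation, grouped by branch."""
    rows = ["\t".join(EVENT_COLUMNS)]
    for branch_id, hist in histories.items():
        for op in hist:
            sg, (s1, s2) = op.source
            tg, t1 = ("", "") if op.target is None else (op.target[0],
                                                         op.target[1][0])
            rows.append("\t".join(map(str, [branch_id, op.kind, op.length,
                                            sg, s1, s2, tg, t1])))
    Path(path).write_text("\n".join(rows) + "\n")


def read_events(path: str | Path) -> dict[str, History]:
    out: dict[str, History] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header != EVENT_COLUMNS:
        raise ValueError(f"unexpected event-log header: {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        b, kind, length, sg, s1, s2, tg, t1 = line.split("\t")
        length = int(length)
        target = None if tg == "" else (tg, (int(t1), int(t1) + length))
        out.setdefault(b, []).append(
            Operation(kind, length, source=(sg, (int(s1), int(s2))),
                      target=target))
    return out


def write_rounds(log_: RoundLog, path: str | Path) -> None:
    rows = ["round\tcost\tnodes_improved"]
    for rnd, cost, improved in log_.entries:
        rows.append(f"{rnd}\t{cost:g}\t{improved}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_results(tree: AssignedTree, log_: RoundLog, config: RunConfig) -> dict[str, Path]:
    """Write assignments, per-round costs and the annotated newick tree."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": out / "assignments.tsv",
        "rounds": out / "rounds.tsv",
        "tree": out / "tree.nwk",
        "config": out / "config.yaml",
    }
    write_assignments(tree, paths["assignments"])
    write_rounds(log_, paths["rounds"])
    write_newick(tree, paths["tree"])
    config.to_yaml(paths["config"])
    for rnd, cost, improved in log_.entries:
        log.info("round %d: total cost %g (%d nodes improved)",
                 rnd, cost, improved)
    return paths
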
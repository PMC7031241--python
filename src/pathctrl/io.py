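"""Readers and writers for edge lists, pathway collections, GMT gene sets
and orthology tables, plus pooling of a collection into one network.

Only *directed* interaction records are retained: the controllability
machinery is defined on directed edges, so records flagged undirected are
dropped at parse time rather than symmetrised.  Identifiers are opaque,
case-sensitive strings; no symbol normalisation is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .network import AnnotationSet, DirectedNetwork, OrthologyMap, PathwayCollection

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: SIF relation names treated as directed by default.
DEFAULT_DIRECTED_RELATIONS = frozenset(
    {"directed", "activates", "inhibits", "phosphorylates", "controls", "->"}
)


class ParseError(ValueError):
    """Malformed record in an input file; carries the 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _read_node_sidecar(path: Path) -> Set[str]:
    """Optional one-identifier-per-line sidecar declaring isolated nodes."""
    nodes: Set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            nodes.add(line)
    return nodes


def read_network(
    path: PathLike,
    dialect: str = "tsv-edgelist",
    header: bool = False,
    directed_relations: Iterable[str] = DEFAULT_DIRECTED_RELATIONS,
    node_list: Optional[PathLike] = None,
) -> DirectedNetwork:
    """Read a directed network from a TSV edge list or SIF file.

    TSV dialect: three tab-separated columns ``source  target  direction``
    with direction in ``{directed, undirected}``; undirected records are
    dropped.  SIF dialect: ``source  relation  target`` with relations in
    ``directed_relations`` kept as directed edges and all others dropped.

    Duplicate directed records collapse to a single edge; self-loops are
    retained.  An empty file yields an empty network.  ``node_list`` may
    point to a sidecar file declaring isolated nodes.
    """
    path = Path(path)
    if dialect not in ("tsv-edgelist", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    directed_relations = frozenset(directed_relations)
    edges: Set[Tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "tsv-edgelist":
                if len(fields) != 3:
                    raise ParseError(path, lineno, f"expected 3 fields, got {len(fields)}")
                src, dst, direction = (f.strip() for f in fields)
                if not src or not dst:
                    raise ParseError(path, lineno, "empty identifier")
                if direction == "directed":
                    edges.add((src, dst))
                elif direction == "undirected":
                    continue
                else:
                    raise ParseError(path, lineno, f"unknown direction flag {direction!r}")
            else:  # sif
                if len(fields) < 3:
                    raise ParseError(path, lineno, f"expected >=3 fields, got {len(fields)}")
                src, relation = fields[0].strip(), fields[1].strip()
                if relation in directed_relations:
                    for dst in (f.strip() for f in fields[2:]):
                        if not dst:
                            raise ParseError(path, lineno, "empty target identifier")
                        edges.add((src, dst))
    extra = _read_node_sidecar(Path(node_list)) if node_list is not None else set()
    return DirectedNetwork.from_edges(edges, extra_nodes=extra)


def write_network(network: DirectedNetwork, path: PathLike, dialect: str = "tsv-edgelist") -> None:
    """Write a network as a sorted edge list (round-trips with read_network).

    Isolated nodes cannot be expressed in either dialect; a sidecar file
    ``<path>.nodes`` is written when the network has any.
    """
    path = Path(path)
    lines: List[str] = []
    for u, v in sorted(network.edges):
        if dialect == "tsv-edgelist":
            lines.append(f"{u}\t{v}\tdirected")
        elif dialect == "sif":
            lines.append(f"{u}\tdirected\t{v}")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("".join(line + "\n" for line in lines))
    isolated = network.nodes - {n for e in network.edges for n in e}
    if isolated:
        Path(str(path) + ".nodes").write_text(
            "".join(n + "\n" for n in sorted(isolated))
        )


def load_collection(
    source: Union[PathLike, Mapping[str, PathLike]],
    min_edges: int = 5,
    dialect: str = "tsv-edgelist",
) -> PathwayCollection:
    """Load a pathway collection from a directory, manifest, or mapping.

    ``source`` may be a directory (every ``*.tsv``/``*.sif`` file becomes a
    pathway named after its stem), a two-column manifest TSV
    ``pathway_id  file_path`` (paths relative to the manifest), or a
    mapping from pathway id to file path.

    Pathways with fewer than ``min_edges`` directed edges after the
    directed-only filter are excluded (logged).  An empty surviving
    collection is an error.
    """
    entries: List[Tuple[str, Path]] = []
    if isinstance(source, Mapping):
        entries = [(str(k), Path(v)) for k, v in source.items()]
    else:
        source = Path(source)
        if source.is_dir():
            suffix = ".sif" if dialect == "sif" else ".tsv"
            entries = [(p.stem, p) for p in sorted(source.glob(f"*{suffix}"))]
        else:
            base = source.parent
            for lineno, raw in enumerate(source.read_text().splitlines(), start=1):
                if not raw.strip() or raw.startswith("#"):
                    continue
                fields = raw.split("\t")
                if len(fields) != 2:
                    raise ParseError(source, lineno, f"expected 2 fields, got {len(fields)}")
                entries.append((fields[0].strip(), base / fields[1].strip()))

    pathways: Dict[str, DirectedNetwork] = {}
    for pid, fpath in entries:
        net = read_network(fpath, dialect=dialect)
        if net.n_edges < min_edges:
            logger.info(
                "excluding pathway %s: %d directed edges < min_edges=%d",
                pid, net.n_edges, min_edges,
            )
            continue
        if pid in pathways:
            raise ValueError(f"duplicate pathway identifier {pid!r}")
        pathways[pid] = net
    if not pathways:
        raise ValueError("empty collection: no pathway met the min_edges threshold")
    return PathwayCollection(pathways)


def pool_collection(collection: PathwayCollection) -> DirectedNetwork:
    """Union of all pathway node sets and (deduplicated) directed edges."""
    if not len(collection):
        raise ValueError("cannot pool an empty collection")
    nodes: Set[str] = set()
    edges: Set[Tuple[str, str]] = set()
    for _, net in collection:
        nodes |= net.nodes
        edges |= net.edges
    return DirectedNetwork(frozenset(nodes), frozenset(edges))


def read_gmt(path: PathLike) -> List[AnnotationSet]:
    """Read annotation sets from a GMT file (name, description, members...).

    Duplicate members within a line are deduplicated; a line with fewer
    than three fields is malformed.
    """
    path = Path(path)
    sets: List[AnnotationSet] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 fields, got {len(fields)}")
        name = fields[0].strip()
        members = frozenset(f.strip() for f in fields[2:] if f.strip())
        if not members:
            raise ParseError(path, lineno, f"annotation set {name!r} has no members")
        sets.append(AnnotationSet(name=name, members=members))
    return sets


def write_gmt(sets: Sequence[AnnotationSet], path: PathLike) -> None:
    lines = [
        "\t".join([s.name, s.name] + sorted(s.members)) for s in sets
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_orthology(path: PathLike) -> OrthologyMap:
    """Read a 3-column TSV ``organism  organism_protein  human_protein``."""
    path = Path(path)
    omap = OrthologyMap()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 fields, got {len(fields)}")
        organism, oprot, hprot = (f.strip() for f in fields)
        if not (organism and oprot and hprot):
            raise ParseError(path, lineno, "empty identifier")
        omap.add(organism, oprot, hprot)
    return omap


def write_orthology(omap: OrthologyMap, path: PathLike) -> None:
    lines = [
        f"{org}\t{o}\t{h}"
        for org in sorted(omap.pairs)
        for o, h in sorted(omap.pairs[org])
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))
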
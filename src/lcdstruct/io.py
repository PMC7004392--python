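"""Readers, writers and dataset-curation steps for all external file formats.

Formats
-------
* **Annotation file** — FASTA-like triplets per chain: three records with
  headers ``>CHAINID sequence``, ``>CHAINID secstr`` and ``>CHAINID disorder``,
  bodies wrapped at 80 columns.  The secstr body uses DSSP codes with any of
  `` -C~`` for coil; the disorder body uses ``X`` (disordered) / ``-``
  (ordered).  Interior spaces in secstr bodies are significant; fully blank
  trailing runs should be written as ``-``.
* **Cluster file** — one homology cluster per line, whitespace-separated chain
  IDs, first member is the quality-sorted representative.
* **Propensity-scale TSV** — ``#name`` / ``#kind`` / ``#orientation`` /
  ``#exclude`` header block followed by ``AA<TAB>value`` rows.
* **Annotation map TSV** — ``chain_id<TAB>annotation_id<TAB>annotation_name``.
* **Tag table TSV** — ``tag_name<TAB>tag_sequence``; exclusion list — one
  chain id per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import AMINO_ACIDS, AA_INDEX, AnnotatedChain, COIL

logger = logging.getLogger("lcdstruct")

_RECORD_KINDS = ("sequence", "secstr", "disorder")
_WRAP = 80

#: Best-effort default table of common expression/purification tags.  Users
#: with a curated tag list should load their own table; entries shorter than
#: four residues are rejected as unsafe to trim.
DEFAULT_TAGS: tuple[tuple[str, str], ...] = (
    ("His6", "HHHHHH"),
    ("His8", "HHHHHHHH"),
    ("His10", "HHHHHHHHHH"),
    ("HA", "YPYDVPDYA"),
    ("FLAG", "DYKDDDDK"),
    ("Myc", "EQKLISEEDL"),
    ("StrepII", "WSHPQFEK"),
    ("S-tag", "KETAAAKFERQHMDS"),
    ("T7", "MASMTGGQQMG"),
    ("V5", "GKPIPNPLLGLDST"),
    ("TEV-site", "ENLYFQG"),
    ("Thrombin-site", "LVPRGS"),
)


class FormatError(ValueError):
    """A file violates its declared schema."""


@dataclass(frozen=True)
class TagTable:
    """Terminal expression/purification tags eligible for trimming."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_TAGS

    def __post_init__(self) -> None:
        for name, seq in self.entries:
            if len(seq) < 4:
                raise FormatError(f"tag {name!r} shorter than 4 residues")
            bad = set(seq) - set(AMINO_ACIDS)
            if bad:
                raise FormatError(f"tag {name!r} has non-canonical letters {bad}")


@dataclass(frozen=True)
class ClusterFile:
    """Ordered homology clusters; first member of each is the representative."""

    clusters: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            for cid in cluster:
                if cid in seen:
                    raise FormatError(f"chain {cid} appears in more than one cluster")
                seen.add(cid)


@dataclass(frozen=True)
class PropensityScale:
    """A named helix or sheet propensity scale over the amino acids.

    ``orientation`` declares whether larger values mean stronger propensity
    (``higher_is_more``) or the reverse; regression code sign-flips
    ``lower_is_more`` scales so all scales share one orientation.
    """

    name: str
    kind: str  # "helix" | "sheet"
    values: tuple[tuple[str, float], ...]
    orientation: str = "higher_is_more"
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "sheet"):
            raise FormatError(f"scale {self.name!r}: kind must be helix|sheet")
        if self.orientation not in ("higher_is_more", "lower_is_more"):
            raise FormatError(f"scale {self.name!r}: bad orientation")
        seen: set[str] = set()
        for aa, _ in self.values:
            if aa not in AA_INDEX:
                raise FormatError(f"scale {self.name!r}: unknown amino acid {aa!r}")
            if aa in seen:
                raise FormatError(f"scale {self.name!r}: duplicate row for {aa}")
            seen.add(aa)

    @property
    def value_map(self) -> dict[str, float]:
        return dict(self.values)

    @property
    def missing(self) -> frozenset[str]:
        """Amino acids the scale does not score."""
        return frozenset(AMINO_ACIDS) - {aa for aa, _ in self.values}

    def oriented_values(self) -> dict[str, float]:
        """Values with ``lower_is_more`` scales sign-flipped."""
        if self.orientation == "lower_is_more":
            logger.info("scale %s: lower_is_more, sign-flipping values", self.name)
            return {aa: -v for aa, v in self.values}
        return dict(self.values)


@dataclass(frozen=True)
class AnnotationMap:
    """Chain-level annotation assignments plus annotation display names."""

    chain_annotations: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def annotations_for(self, chain_id: str) -> frozenset[str]:
        return self.chain_annotations.get(chain_id, frozenset())

    @property
    def all_annotations(self) -> frozenset[str]:
        out: set[str] = set()
        for anns in self.chain_annotations.values():
            out |= anns
        return frozenset(out)


# ---------------------------------------------------------------------------
# Annotation (triplet-FASTA) files


def read_annotated_chains(path: str | Path) -> list[AnnotatedChain]:
    """Parse a triplet-FASTA annotation file into :class:`AnnotatedChain` s.

    Residues flagged in the disorder record get ``disorder_mask=True``
    regardless of their secstr character; unknown sequence letters map to 'X'.

    Raises
    ------
    FormatError
        If a chain is missing one of its three records or its records have
        mismatched lengths.
    """
    records: dict[str, dict[str, str]] = {}
    order: list[str] = []
    header: tuple[str, str] | None = None
    body: list[str] = []

    def flush() -> None:
        if header is None:
            return
        cid, kind = header
        records.setdefault(cid, {})
        if kind in records[cid]:
            raise FormatError(f"chain {cid}: duplicate {kind} record")
        records[cid][kind] = "".join(body)

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                if len(parts) != 2 or parts[1] not in _RECORD_KINDS:
                    raise FormatError(f"bad header line {line!r}")
                header = (parts[0], parts[1])
                if parts[0] not in records:
                    order.append(parts[0])
                body = []
            else:
                if header is None and line.strip():
                    raise FormatError("body text before any header")
                body.append(line)
    flush()

    chains: list[AnnotatedChain] = []
    for cid in order:
        recs = records[cid]
        missing = [k for k in _RECORD_KINDS if k not in recs]
        if missing:
            raise FormatError(f"chain {cid}: missing record(s) {missing}")
        seq, ss, dis = (recs[k] for k in _RECORD_KINDS)
        if not (len(seq) == len(ss) == len(dis)):
            raise FormatError(
                f"chain {cid}: record lengths differ "
                f"(sequence {len(seq)}, secstr {len(ss)}, disorder {len(dis)})"
            )
        bad = set(dis) - {"X", "-"}
        if bad:
            raise FormatError(f"chain {cid}: bad disorder characters {bad}")
        mask = np.frombuffer(dis.encode("latin-1"), dtype=np.uint8) == ord("X")
        chains.append(AnnotatedChain(cid, seq, ss, mask))
    return chains


def write_annotated_chains(chains: Iterable[AnnotatedChain], path: str | Path) -> None:
    """Write chains in the triplet-FASTA dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        for chain in chains:
            dis = "".join("X" if d else "-" for d in chain.disorder_mask)
            for kind, body in (
                ("sequence", chain.sequence),
                ("secstr", chain.ss_states),
                ("disorder", dis),
            ):
                fh.write(f">{chain.chain_id} {kind}\n")
                for i in range(0, len(body), _WRAP):
                    fh.write(body[i : i + _WRAP] + "\n")


# ---------------------------------------------------------------------------
# Curation steps


def read_cluster_file(path: str | Path) -> ClusterFile:
    clusters: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            members = tuple(line.split())
            if not members:
                logger.warning("%s:%d: empty cluster line skipped", path, lineno)
                continue
            clusters.append(members)
    return ClusterFile(tuple(clusters))


def select_representatives(
    chains: Sequence[AnnotatedChain], clusters: ClusterFile
) -> list[AnnotatedChain]:
    """Keep one chain per homology cluster.

    The first listed member present in ``chains`` is retained (the cluster
    file is pre-sorted by structure quality); chains absent from every cluster
    are dropped.  Output order follows the cluster file.
    """
    by_id = {c.chain_id: c for c in chains}
    out: list[AnnotatedChain] = []
    for cluster in clusters.clusters:
        for rank, cid in enumerate(cluster):
            if cid in by_id:
                if rank > 0:
                    logger.warning(
                        "cluster %s: representative %s absent, using %s",
                        cluster[0], cluster[0], cid,
                    )
                out.append(by_id[cid])
                break
        else:
            logger.warning("cluster %s: no member present in input", cluster[0])
    return out


def trim_terminal_tags(
    chain: AnnotatedChain,
    tags: TagTable | None = None,
    margin: int = 20,
) -> AnnotatedChain | None:
    """Remove terminal expression tags (and anything terminal of them).

    A tag occurrence overlapping the first ``margin`` residues is removed
    together with everything N-terminal of it; one overlapping the final
    ``margin`` residues is removed with everything C-terminal of it.  The
    longest matching tag wins; at most one trim per terminus.  Returns ``None``
    (with a logged warning) if trimming would empty the chain.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    tags = tags or TagTable()
    seq = chain.sequence
    n = len(seq)

    def occurrences(tag: str) -> list[int]:
        out, i = [], seq.find(tag)
        while i != -1:
            out.append(i)
            i = seq.find(tag, i + 1)
        return out

    # Longest tag first so the longest qualifying match wins; within one tag
    # the innermost qualifying occurrence is taken (maximal removal), which
    # makes trimming idempotent when tags do not recur inside the chain body.
    ordered = sorted(tags.entries, key=lambda e: -len(e[1]))
    start, end = 0, n
    for _, tag in ordered:
        hits = [p for p in occurrences(tag) if p < margin]
        if hits:
            start = max(hits) + len(tag)
            break
    for _, tag in ordered:
        hits = [p for p in occurrences(tag) if p + len(tag) > n - margin]
        hits = [p for p in hits if p >= start]
        if hits:
            end = min(hits)
            break
    if start == 0 and end == n:
        return chain
    if start >= end:
        logger.warning("%s: tag trimming would empty the chain; dropped", chain.chain_id)
        return None
    return chain.subchain(start, end)


def apply_exclusions(
    chains: Sequence[AnnotatedChain], excluded_ids: set[str]
) -> list[AnnotatedChain]:
    """Drop chains whose id is in ``excluded_ids``; order preserved."""
    present = {c.chain_id for c in chains}
    for cid in sorted(excluded_ids - present):
        logger.info("exclusion id %s not present in input", cid)
    return [c for c in chains if c.chain_id not in excluded_ids]


# ---------------------------------------------------------------------------
# Tabular inputs


def read_propensity_scale(path: str | Path) -> PropensityScale:
    """Read a single propensity-scale TSV (see module docstring for schema)."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                if not val:
                    key, _, val = line[1:].partition(" ")
                meta[key.strip()] = val.strip()
                continue
            aa, _, val = line.partition("\t")
            try:
                rows.append((aa.strip(), float(val)))
            except ValueError as err:
                raise FormatError(f"{path}: bad value row {line!r}") from err
    if "name" not in meta or "kind" not in meta:
        raise FormatError(f"{path}: missing #name or #kind header")
    excluded = frozenset(
        a.strip() for a in meta.get("exclude", "").split(",") if a.strip()
    )
    return PropensityScale(
        name=meta["name"],
        kind=meta["kind"],
        values=tuple(rows),
        orientation=meta.get("orientation", "higher_is_more"),
        excluded=excluded,
    )


def read_propensity_scales(path: str | Path) -> list[PropensityScale]:
    """Read all ``*.tsv`` scale files in a directory (or one file)."""
    p = Path(path)
    if p.is_dir():
        return [read_propensity_scale(f) for f in sorted(p.glob("*.tsv"))]
    return [read_propensity_scale(p)]


def write_propensity_scale(scale: PropensityScale, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name\t{scale.name}\n#kind\t{scale.kind}\n")
        fh.write(f"#orientation\t{scale.orientation}\n")
        fh.write(f"#exclude\t{','.join(sorted(scale.excluded))}\n")
        for aa, val in scale.values:
            fh.write(f"{aa}\t{val!r}\n")


def read_annotation_map(path: str | Path) -> AnnotationMap:
    chain_annotations: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab fields")
            cid, ann = parts[0], parts[1]
            chain_annotations.setdefault(cid, set()).add(ann)
            if len(parts) >= 3 and parts[2]:
                names[ann] = parts[2]
    return AnnotationMap(
        {cid: frozenset(a) for cid, a in chain_annotations.items()}, names
    )


def write_annotation_map(annmap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(annmap.chain_annotations):
            for ann in sorted(annmap.chain_annotations[cid]):
                fh.write(f"{cid}\t{ann}\t{annmap.names.get(ann, '')}\n")


def read_tag_table(path: str | Path) -> TagTable:
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, _, seq = line.partition("\t")
            entries.append((name, seq.strip()))
    return TagTable(tuple(entries))


def read_exclusion_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_cluster_file(clusters: ClusterFile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cluster in clusters.clusters:
            fh.write(" ".join(cluster) + "\n")
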
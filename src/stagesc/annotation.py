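"""Rule-based reconciliation of two gene-level genome annotations.

An old and a new annotation (gene records from GTF) are joined into
connected components of the interval-overlap graph between sources; each
component is then resolved with the replace / reject / compound rules:

* 1 old, 1 new  -> the new model replaces the old (``replace``);
* 1 old, >=2 new -> the split is rejected, the old model is kept
  (``reject_new``);
* >=2 old, 1 new -> the new compound model is kept (``compound_new``);
* one-sided components keep whatever source they contain;
* many-to-many components (>=2 on both sides) are not covered by the three
  rules; the default keeps the old models and flags the component as
  ambiguous (configurable).

Coordinates are handled 0-based half-open internally; GTF's 1-based
inclusive convention is converted at the I/O boundary, so touching-but-not-
overlapping models ([100,200] and [201,300]) land in separate components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneModel",
    "ReconciledSet",
    "read_gtf",
    "write_gtf",
    "overlap_components",
    "reconcile",
]


class GTFError(ValueError):
    pass


@dataclass
class GeneModel:
    """One gene record: 1-based inclusive coordinates, strand, and source.

    ``raw_lines`` carries the original GTF lines (the gene line plus any
    attached child features) verbatim so writes round-trip byte-identically.
    """

    id: str
    seqid: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    source: str  # "old" or "new"
    attributes: str = ""
    raw_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GTFError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise GTFError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def half_open(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return (self.start - 1, self.end)


@dataclass
class ReconciledSet:
    """Retained models plus the per-component decision record."""

    retained: list[GeneModel]
    decisions: pd.DataFrame  # component, old_ids, new_ids, rule, ambiguous


def _parse_gene_id(attributes: str) -> str:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    raise GTFError(f"no gene_id in attributes: {attributes[:80]!r}")


def read_gtf(path, source: str = "old") -> list[GeneModel]:
    """Read gene-level records from a GTF file.

    Only feature type ``gene`` becomes a :class:`GeneModel`; other feature
    lines are attached verbatim to the preceding gene with the same gene_id.
    Unparseable lines raise with their line number.
    """
    models: list[GeneModel] = []
    by_id: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 9:
                raise GTFError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            seqid, _src, feature, start_s, end_s, _score, strand, _frame, attrs = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_id = _parse_gene_id(attrs)
            if feature == "gene":
                try:
                    model = GeneModel(
                        id=gene_id, seqid=seqid, strand=strand,
                        start=start, end=end, source=source,
                        attributes=attrs, raw_lines=[stripped],
                    )
                except GTFError as exc:
                    raise GTFError(f"{path}:{lineno}: {exc}") from exc
                if gene_id in by_id:
                    raise GTFError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
                models.append(model)
                by_id[gene_id] = model
            else:
                if gene_id not in by_id:
                    raise GTFError(
                        f"{path}:{lineno}: feature for unknown gene_id {gene_id!r}"
                    )
                by_id[gene_id].raw_lines.append(stripped)
    return models


def write_gtf(models: list[GeneModel], path) -> Path:
    """Write models back out; gene lines are emitted verbatim."""
    path = Path(path)
    with open(path, "w") as fh:
        for m in models:
            for line in m.raw_lines:
                fh.write(line + "\n")
    return path


def overlap_components(
    old: list[GeneModel], new: list[GeneModel], strand_aware: bool = True
) -> list[tuple[list[GeneModel], list[GeneModel]]]:
    """Connected components of the old-new interval-overlap graph.

    Edges connect an old and a new model on the same seqid (and strand when
    ``strand_aware``) whose half-open intervals intersect with positive
    length; components close transitively, so an old-new-old chain is one
    component.  Models overlapping nothing from the other source form
    singleton components.  The partition is independent of input order:
    components are returned sorted by (seqid, start, id) of their first
    model and every input model appears in exactly one component.
    """
    all_models = list(old) + list(new)
    parent = list(range(len(all_models)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def group_key(m: GeneModel):
        return (m.seqid, m.strand) if strand_aware else (m.seqid,)

    by_group: dict[tuple, list[int]] = {}
    for i, m in enumerate(all_models):
        by_group.setdefault(group_key(m), []).append(i)
    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: all_models[i].half_open)
        for a_pos, i in enumerate(idxs):
            s_i, e_i = all_models[i].half_open
            for j in idxs[a_pos + 1:]:
                s_j, e_j = all_models[j].half_open
                if s_j >= e_i:
                    break
                if all_models[i].source != all_models[j].source:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(all_models)):
        groups.setdefault(find(i), []).append(i)

    def sort_key(m: GeneModel):
        return (m.seqid, m.start, m.end, m.id)

    components = []
    for idxs in groups.values():
        olds = sorted((all_models[i] for i in idxs if all_models[i].source == "old"),
                      key=sort_key)
        news = sorted((all_models[i] for i in idxs if all_models[i].source == "new"),
                      key=sort_key)
        components.append((olds, news))
    components.sort(key=lambda c: sort_key((c[0] + c[1])[0]))
    return components


def reconcile(
    components: list[tuple[list[GeneModel], list[GeneModel]]],
    many_many: str = "keep_old",
) -> ReconciledSet:
    """Apply the replace / reject / compound rules per component.

    Within one component the retained models come from exactly one source.
    ``many_many`` controls the uncovered >=2-vs->=2 case: ``"keep_old"``
    (default, flagged ambiguous) or ``"keep_new"``.
    """
    if many_many not in {"keep_old", "keep_new"}:
        raise ValueError("many_many must be 'keep_old' or 'keep_new'")
    retained: list[GeneModel] = []
    rows = []
    for comp_id, (olds, news) in enumerate(components):
        n_old, n_new = len(olds), len(news)
        ambiguous = False
        if n_old == 1 and n_new == 1:
            rule, keep = "replace", news
        elif n_old == 1 and n_new >= 2:
            rule, keep = "reject_new", olds
        elif n_old >= 2 and n_new == 1:
            rule, keep = "compound_new", news
        elif n_old == 0:
            rule, keep = "keep_new_only", news
        elif n_new == 0:
            rule, keep = "keep_old_only", olds
        else:  # many-to-many: not covered by the three rules
            ambiguous = True
            if many_many == "keep_old":
                rule, keep = "keep_old_ambiguous", olds
            else:
                rule, keep = "keep_new_ambiguous", news
        retained.extend(keep)
        rows.append(
            {
                "component": comp_id,
                "old_ids": ";".join(m.id for m in olds),
                "new_ids": ";".join(m.id for m in news),
                "rule": rule,
                "ambiguous": ambiguous,
            }
        )
    decisions = pd.DataFrame(
        rows, columns=["component", "old_ids", "new_ids", "rule", "ambiguous"]
    )
    return ReconciledSet(retained=retained, decisions=decisions)
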
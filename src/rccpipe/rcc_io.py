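"""Reading and writing NanoString RCC lane files and plain count-matrix tables.

An RCC ("reporter code count") file is the per-lane text output of the
nCounter digital analyzer: a handful of ``<Section>…</Section>`` blocks of
comma-separated key/value pairs, ending in a ``<Code_Summary>`` block with one
``CodeClass,Name,Accession,Count`` row per probe.  This module parses those
files into :class:`RccLane` records, assembles multiple lanes into a
:class:`CountMatrix`, and round-trips both RCC text and a TSV exchange format.

Probe identity is the pair ``(code_class, name)``; accession strings are
carried through but never used as a join key.  Mismatched probe sets across
lanes are a hard error — counts are never silently reordered or deduplicated.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Negative", "Positive")

#: sections whose comma-separated key,value rows are parsed into attribute maps
_ATTR_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes")


class RccParseError(ValueError):
    """Raised when an RCC stream violates the section-tagged CSV dialect."""


@dataclass(frozen=True)
class ProbeRecord:
    """One probe row of a Code_Summary block."""

    code_class: str
    name: str
    accession: str
    count: int

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValueError(f"unknown code class {self.code_class!r} for probe {self.name!r}")
        if not self.name:
            raise ValueError("probe name must be nonempty")
        if self.count < 0:
            raise ValueError(f"negative count for probe {self.name!r}")


@dataclass
class RccLane:
    """A parsed RCC lane: one sample's probe counts plus file metadata.

    ``header_attrs``, ``sample_attrs`` and ``lane_attrs`` hold the key→value
    rows of the corresponding sections (``sample_attrs`` excludes the ``ID``
    row, which is surfaced as :attr:`sample_id`).  Unknown sections are kept
    verbatim in ``extra_sections`` so that write→parse is the identity even
    across vendor dialect drift.
    """

    sample_id: str
    header_attrs: dict[str, str] = field(default_factory=dict)
    probes: list[ProbeRecord] = field(default_factory=list)
    sample_attrs: dict[str, str] = field(default_factory=dict)
    lane_attrs: dict[str, str] = field(default_factory=dict)
    extra_sections: dict[str, str] = field(default_factory=dict)

    def probe_names(self) -> list[str]:
        return [p.name for p in self.probes]

    def counts_by_class(self, code_class: str) -> list[int]:
        return [p.count for p in self.probes if p.code_class == code_class]


def parse_rcc(source: io.TextIOBase | str) -> RccLane:
    """Parse RCC text (a stream or a string) into an :class:`RccLane`.

    Raises :class:`RccParseError` naming the offending line or probe on
    malformed section tags, non-integer counts, or duplicate probe names.
    """
    text = source if isinstance(source, str) else source.read()
    sections: dict[str, list[str]] = {}
    order: list[str] = []
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</"):
            name = line[2:-1]
            if not line.endswith(">") or current != name:
                raise RccParseError(f"line {lineno}: unexpected closing tag {line!r}")
            current = None
        elif line.startswith("<") and line.endswith(">"):
            if current is not None:
                raise RccParseError(f"line {lineno}: nested section tag {line!r}")
            current = line[1:-1]
            if current in sections:
                raise RccParseError(f"line {lineno}: duplicate section {current!r}")
            sections[current] = []
            order.append(current)
        else:
            if current is None:
                raise RccParseError(f"line {lineno}: content outside any section: {line!r}")
            sections[current].append(line)
    if current is not None:
        raise RccParseError(f"section {current!r} never closed")
    if "Code_Summary" not in sections:
        raise RccParseError("missing <Code_Summary> section")

    attrs = {
        name: dict(_split_kv(row) for row in sections.get(name, []) if row.lower() != "codeclass,name,accession,count")
        for name in _ATTR_SECTIONS
    }
    sample_attrs = attrs["Sample_Attributes"]
    sample_id = sample_attrs.pop("ID", "")

    probes: list[ProbeRecord] = []
    seen: set[str] = set()
    for row in sections["Code_Summary"]:
        if row.lower().startswith("codeclass,"):
            continue  # column header row
        parts = row.split(",")
        if len(parts) != 4:
            raise RccParseError(f"malformed Code_Summary row: {row!r}")
        code_class, name, accession, count_str = (p.strip() for p in parts)
        try:
            count = int(count_str)
        except ValueError:
            raise RccParseError(f"non-integer count {count_str!r} for probe {name!r}") from None
        if name in seen:
            raise RccParseError(f"duplicate probe name {name!r}")
        seen.add(name)
        probes.append(ProbeRecord(code_class, name, accession, count))

    extra = {
        name: "\n".join(sections[name])
        for name in order
        if name not in _ATTR_SECTIONS and name != "Code_Summary"
    }
    return RccLane(
        sample_id=sample_id,
        header_attrs=attrs["Header"],
        probes=probes,
        sample_attrs=sample_attrs,
        lane_attrs=attrs["Lane_Attributes"],
        extra_sections=extra,
    )


def _split_kv(row: str) -> tuple[str, str]:
    key, _, value = row.partition(",")
    return key.strip(), value


def write_rcc(lane: RccLane, sink: io.TextIOBase) -> None:
    """Serialize ``lane`` so that ``parse_rcc`` recovers it exactly."""
    def section(name: str, rows: Iterable[str]) -> None:
        sink.write(f"<{name}>\n")
        for row in rows:
            sink.write(row + "\n")
        sink.write(f"</{name}>\n")

    section("Header", (f"{k},{v}" for k, v in lane.header_attrs.items()))
    sample_rows = [f"ID,{lane.sample_id}"] + [f"{k},{v}" for k, v in lane.sample_attrs.items()]
    section("Sample_Attributes", sample_rows)
    section("Lane_Attributes", (f"{k},{v}" for k, v in lane.lane_attrs.items()))
    code_rows = ["CodeClass,Name,Accession,Count"] + [
        f"{p.code_class},{p.name},{p.accession},{p.count}" for p in lane.probes
    ]
    section("Code_Summary", code_rows)
    for name, body in lane.extra_sections.items():
        section(name, body.splitlines())


def read_rcc(path: str | Path) -> RccLane:
    with open(path, encoding="utf-8") as fh:
        return parse_rcc(fh)


def write_rcc_file(lane: RccLane, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        write_rcc(lane, fh)


@dataclass
class CountMatrix:
    """Probe-by-sample raw counts with probe class labels and group labels.

    ``counts`` is an integer DataFrame indexed by probe name with one column
    per sample; ``probe_classes`` is a parallel Series over the same index;
    ``groups`` maps sample_id → "case" / "control" (may be None until
    differential expression is run).
    """

    counts: pd.DataFrame
    probe_classes: pd.Series
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probe_classes.index):
            raise ValueError("counts index and probe_classes index differ")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def probe_names(self) -> list[str]:
        return list(self.counts.index)

    def names_of_class(self, code_class: str) -> list[str]:
        return list(self.probe_classes.index[self.probe_classes == code_class])

    def class_counts(self, code_class: str) -> pd.DataFrame:
        """Count rows restricted to one probe class."""
        return self.counts.loc[self.probe_classes == code_class]

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("no group labels attached")
        return [s for s in self.sample_ids if self.groups.get(s) == group]

    def require_groups(self) -> None:
        if self.groups is None:
            raise ValueError("group labels required but not attached")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")


def assemble_matrix(lanes: Sequence[RccLane], groups: Mapping[str, str] | None = None) -> CountMatrix:
    """Stack lanes (columns, in the order given) into a :class:`CountMatrix`.

    All lanes must carry an identical (class, name) probe sequence; a mismatch
    raises with the symmetric difference listed.  A sample absent from
    ``groups`` warns here and errors later, at differential-expression time.
    """
    if not lanes:
        raise ValueError("no lanes given")
    ref = [(p.code_class, p.name) for p in lanes[0].probes]
    for lane in lanes[1:]:
        ids = [(p.code_class, p.name) for p in lane.probes]
        if ids != ref:
            diff = set(ids) ^ set(ref)
            raise ValueError(
                f"probe set of lane {lane.sample_id!r} differs from {lanes[0].sample_id!r}"
                f" (symmetric difference or order change: {sorted(diff) if diff else 'probe order permuted'})"
            )
    index = pd.Index([name for _, name in ref], name="probe")
    counts = pd.DataFrame(
        {lane.sample_id: [p.count for p in lane.probes] for lane in lanes},
        index=index,
        dtype=int,
    )
    classes = pd.Series([cc for cc, _ in ref], index=index, name="code_class")
    group_map = dict(groups) if groups is not None else None
    if group_map is not None:
        missing = [lane.sample_id for lane in lanes if lane.sample_id not in group_map]
        if missing:
            warnings.warn(f"samples missing from group map: {missing}", stacklevel=2)
    return CountMatrix(counts=counts, probe_classes=classes, groups=group_map)


def matrix_to_lanes(matrix: CountMatrix) -> list[RccLane]:
    """Explode a matrix back into one RccLane per sample (fixture emission)."""
    lanes = []
    for sample in matrix.sample_ids:
        probes = [
            ProbeRecord(matrix.probe_classes[name], name, "synthetic", int(matrix.counts.at[name, sample]))
            for name in matrix.probe_names
        ]
        lanes.append(RccLane(sample_id=sample, header_attrs={"FileVersion": "1.7"}, probes=probes))
    return lanes


# ---------------------------------------------------------------------------
# TSV exchange format: probe, class, then one column per sample.

def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "class", matrix.probe_classes)
    out.to_csv(path, sep="\t", index_label="probe")


def read_counts_tsv(path: str | Path, groups: Mapping[str, str] | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe")
    classes = df.pop("class")
    return CountMatrix(counts=df.astype(int), probe_classes=classes, groups=dict(groups) if groups else None)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, group) → group map."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError("sample sheet needs two columns: sample_id, group")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_sample_sheet(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}).to_csv(
        path, sep="\t", index=False
    )
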
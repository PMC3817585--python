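"""Sequence and table input/output.

Reads mature-sequence FASTA (RNA or DNA), extracts seed windows (the 6-mer
at positions 2–7 of the mature sequence by default, 1-based inclusive),
parses reference family tables, and writes/reads the tool's tabular outputs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .scoring import Grouping

logger = logging.getLogger(__name__)

_RNA = set("ACGU")
_RNA_OR_DNA = set("ACGUT")


class SeedRecord(NamedTuple):
    """One miRNA identifier and its fixed-length seed over {A, C, G, U}."""

    id: str
    seed: str


@dataclass
class FamilyTable:
    """Reference families: family id → set of member ids.

    A member id may belong to at most one family; optional per-family
    accessions are kept alongside.
    """

    entries: dict[str, set[str]]
    accessions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        offenders = []
        for fam, members in self.entries.items():
            if not members:
                raise ValueError(f"family {fam!r} has no members")
            for m in members:
                if m in seen and seen[m] != fam:
                    offenders.append((m, seen[m], fam))
                seen[m] = fam
        if offenders:
            raise ValueError(
                "member ids appear in more than one family: "
                + "; ".join(f"{m} in {a} and {b}" for m, a, b in offenders)
            )


class FastaParseError(ValueError):
    pass


def read_fasta(
    path,
    alphabet_policy: str = "dna_to_rna",
    skip_invalid: bool = False,
) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` pairs.

    Ids are the first whitespace-delimited header token and must be unique.
    Sequences are uppercased; with ``alphabet_policy="dna_to_rna"`` every T
    is mapped to U, with ``"strict"`` only {A, C, G, U} are accepted as-is.
    A record with a character outside the allowed set (e.g. the ambiguity
    code N) is an error, or is skipped with a warning when
    ``skip_invalid=True``.
    """
    if alphabet_policy not in ("strict", "dna_to_rna"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    allowed = _RNA if alphabet_policy == "strict" else _RNA_OR_DNA

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected a '>' header before "
                        "sequence data"
                    )
                break

    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rec_id = header.split()[0] if header.split() else header
            if rec_id in seen:
                raise ValueError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            seq = seq.upper()
            bad = sorted(set(seq) - allowed)
            if bad:
                if skip_invalid:
                    logger.warning(
                        "skipping record %s: characters %s outside the "
                        "allowed alphabet", rec_id, bad,
                    )
                    continue
                raise ValueError(
                    f"record {rec_id!r} contains character {bad[0]!r} outside "
                    f"the allowed alphabet {sorted(allowed)}"
                )
            if alphabet_policy == "dna_to_rna":
                seq = seq.replace("T", "U")
            out.append((rec_id, seq))
    return out


def extract_seed(
    full_sequence: str,
    start: int = 2,
    length: int = 6,
    seq_id: Optional[str] = None,
) -> str:
    """Seed window covering 1-based positions ``start .. start+length-1``.

    Defaults give the canonical seed region: positions 2–7 of the mature
    sequence.
    """
    if start < 1 or length < 1:
        raise ValueError("start and length must be positive")
    if len(full_sequence) < start + length - 1:
        who = f" (record {seq_id})" if seq_id else ""
        raise ValueError(
            f"sequence of length {len(full_sequence)}{who} is too short for a "
            f"window at positions {start}..{start + length - 1}"
        )
    return full_sequence[start - 1 : start + length - 1]


def load_seed_records(
    path,
    start: int = 2,
    length: int = 6,
    alphabet_policy: str = "dna_to_rna",
    skip_invalid: bool = False,
    id_prefixes: Optional[list[str]] = None,
) -> list[SeedRecord]:
    """FASTA → seed records: read, normalize, optionally filter, extract.

    ``id_prefixes`` keeps only records whose id starts with one of the given
    prefixes (e.g. ``["hsa-", "mmu-"]`` for a species whitelist).
    """
    records = read_fasta(path, alphabet_policy, skip_invalid)
    if id_prefixes:
        records = [
            (rid, seq)
            for rid, seq in records
            if any(rid.startswith(p) for p in id_prefixes)
        ]
    return [
        SeedRecord(rid, extract_seed(seq, start, length, seq_id=rid))
        for rid, seq in records
    ]


def read_family_table(path) -> FamilyTable:
    """Parse a 2–3 column TSV (family_id, member_id[, accession]).

    Lines starting with '#' are ignored. Empty tables and members listed
    under two families are errors.
    """
    entries: dict[str, set[str]] = {}
    accessions: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(
            (line for line in fh if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        for row in reader:
            if len(row) < 2:
                raise ValueError(
                    f"{path}: family table rows need >= 2 columns; got {row}"
                )
            fam, member = row[0].strip(), row[1].strip()
            entries.setdefault(fam, set()).add(member)
            if len(row) >= 3 and row[2].strip():
                accessions[fam] = row[2].strip()
    if not entries:
        raise ValueError(f"{path}: family table is empty")
    return FamilyTable(entries=entries, accessions=accessions)


def write_assignments(grouping: Grouping, responsibilities, path) -> None:
    """Write the per-record assignment TSV.

    Columns: id, seed, group_index (0-based), max_responsibility (6 decimal
    places); one row per record in input order.
    """
    z = np.asarray(responsibilities, dtype=float)
    seeds = grouping.seeds if grouping.seeds is not None else [""] * len(grouping.ids)
    with open(path, "w", newline="") as fh:
        fh.write("id\tseed\tgroup_index\tmax_responsibility\n")
        for m, (rid, seed) in enumerate(zip(grouping.ids, seeds)):
            fh.write(
                f"{rid}\t{seed}\t{grouping.labels[m]}\t{z[m].max():.6f}\n"
            )


def read_assignments(path) -> Grouping:
    """Read an assignment TSV back into a :class:`~mirmix.scoring.Grouping`."""
    ids: list[str] = []
    seeds: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "seed", "group_index"]:
            raise ValueError(f"{path}: not an assignments TSV (header {header})")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            seeds.append(parts[1])
            labels.append(int(parts[2]))
    k = max(labels) + 1 if labels else 0
    return Grouping(ids=ids, labels=np.asarray(labels, dtype=int), k=k, seeds=seeds)


def write_group_scores(table, global_means, path) -> None:
    """Write the per-group score TSV plus a trailing 'all' summary row.

    Undefined silhouettes (single non-empty group) are written as ``NA``.
    """

    def _fmt(x) -> str:
        return "NA" if x != x else f"{x:.6f}"  # NaN != NaN

    with open(path, "w", newline="") as fh:
        fh.write("group_index\tn_members\tmean_score_S\tmean_score_M\n")
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.group_index}\t{row.n_members}\t"
                f"{_fmt(row.mean_score_S)}\t{_fmt(row.mean_score_M)}\n"
            )
        fh.write(
            f"all\t{global_means['n']}\t{_fmt(global_means['mean_score_S'])}\t"
            f"{_fmt(global_means['mean_score_M'])}\n"
        )


def write_enrichment(table, path, group_prefix: str = "") -> None:
    """Write the family-enrichment TSV, sorted by family id."""
    with open(path, "w", newline="") as fh:
        fh.write("family_id\tbest_group\toverlap\tfamily_size\tn_missing\tenrichment\n")
        for row in table.sort_values("family_id").itertuples(index=False):
            fh.write(
                f"{row.family_id}\t{group_prefix}{row.best_group}\t{row.overlap}\t"
                f"{row.family_size}\t{row.n_missing}\t{row.enrichment}\n"
            )
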
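"""Frameshift and premature-stop lesion detection in aligned coding
sequences, and sharing of lesions between designated sister-species pairs.

Pseudogenization of vision genes in obligate subterranean lineages leaves
two easily detectable lesion types in a codon alignment: insertion/deletion
runs whose length is not a multiple of three (frameshifts) and stop codons
upstream of the natural terminal stop.  Codon coordinates are projected
from a designated reference sequence, so insertions relative to the
reference never shift downstream codon indices — lesion identity is then
robust to realignment, which is what makes "the same lesion in both
members of a sister pair" a meaningful statement.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "CodingAlignment",
    "DeleteriousCall",
    "SharedMutationReport",
    "STANDARD_STOPS",
    "detect_premature_stops",
    "detect_frameshifts",
    "scan_alignment",
    "shared_deleterious",
    "read_alignment_fasta",
    "calls_to_tsv",
    "shared_report_json",
]

#: standard nuclear genetic code stop codons
STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})

_ALPHABET = set("ACGTN-")


class CodingAlignment:
    """Equal-length gapped nucleotide sequences with a designated reference.

    The reference defines the reading frame: after skipping
    ``frame_offset`` reference bases, its ungapped length must be a
    multiple of three, and it must contain no internal stop codon (it is
    required to be a valid ORF).  Allowed characters: A, C, G, T, N, '-'.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        reference_id: str,
        frame_offset: int = 0,
        stop_codons: frozenset[str] = STANDARD_STOPS,
    ):
        if reference_id not in sequences:
            raise ValueError(f"reference {reference_id!r} not among the sequences")
        if frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.reference_id = reference_id
        self.frame_offset = frame_offset
        self.stop_codons = frozenset(stop_codons)

        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.n_columns = lengths.pop()
        for sid, s in self.sequences.items():
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"sequence {sid!r} has invalid characters {sorted(bad)}")

        ref = self.sequences[reference_id]
        ref_cols = [c for c, ch in enumerate(ref) if ch != "-"]
        ref_cols = ref_cols[frame_offset:]
        if len(ref_cols) < 3 or len(ref_cols) % 3 != 0:
            raise ValueError(
                "reference ungapped length after the frame offset must be a "
                f"positive multiple of 3, got {len(ref_cols)}"
            )
        #: per reference codon, the three alignment columns it occupies (0-based)
        self.codon_columns: list[tuple[int, int, int]] = [
            (ref_cols[i], ref_cols[i + 1], ref_cols[i + 2])
            for i in range(0, len(ref_cols), 3)
        ]
        self.n_codons = len(self.codon_columns)
        for ci, cols in enumerate(self.codon_columns[:-1]):
            codon = "".join(ref[c] for c in cols)
            if codon in self.stop_codons:
                raise ValueError(
                    f"reference not a valid ORF: internal stop {codon} at codon {ci + 1}"
                )

    @property
    def query_ids(self) -> list[str]:
        return [s for s in self.sequences if s != self.reference_id]

    def codon_of_column(self, col: int) -> int | None:
        """1-based reference codon index containing (or, for insertion
        columns, immediately following) a 0-based alignment column."""
        for ci, cols in enumerate(self.codon_columns):
            if col <= cols[2]:
                return ci + 1
        return self.n_codons


@dataclass(frozen=True)
class DeleteriousCall:
    """One lesion in one sequence.

    ``column`` is the 1-based alignment column where the lesion starts,
    ``codon`` the 1-based reference codon index.  ``detail`` is the stop
    triplet for premature stops and the indel length mod 3 (1 or 2) for
    frameshifts.  ``post_frameshift`` flags stops downstream of an earlier
    frameshift in the same sequence.
    """

    sequence_id: str
    kind: str  # "frameshift" | "premature_stop"
    column: int
    codon: int
    detail: str
    post_frameshift: bool = False

    def key(self) -> tuple:
        """Identity used for sharing between sequences: stops match on the
        reference codon, frameshifts on (start column, shift)."""
        if self.kind == "premature_stop":
            return ("premature_stop", self.codon)
        return ("frameshift", self.column, self.detail)


def detect_premature_stops(aln: CodingAlignment) -> list[DeleteriousCall]:
    """Stop codons strictly before the reference's terminal codon.

    Every non-reference sequence is read in the frame projected from the
    reference (codon = the query characters in the three alignment columns
    of each reference codon).  Codons containing a gap or N are not called.
    """
    fs_by_seq: dict[str, list[DeleteriousCall]] = {}
    for call in detect_frameshifts(aln):
        fs_by_seq.setdefault(call.sequence_id, []).append(call)
    calls: list[DeleteriousCall] = []
    for sid in aln.query_ids:
        seq = aln.sequences[sid]
        fs_cols = [c.column for c in fs_by_seq.get(sid, [])]
        for ci, cols in enumerate(aln.codon_columns[:-1]):  # exclude terminal codon
            codon = "".join(seq[c] for c in cols)
            if "-" in codon or "N" in codon:
                continue
            if codon in aln.stop_codons:
                col1 = cols[0] + 1
                calls.append(
                    DeleteriousCall(
                        sequence_id=sid,
                        kind="premature_stop",
                        column=col1,
                        codon=ci + 1,
                        detail=codon,
                        post_frameshift=any(fc < col1 for fc in fs_cols),
                    )
                )
    return calls


def detect_frameshifts(aln: CodingAlignment) -> list[DeleteriousCall]:
    """Indel runs relative to the reference whose length mod 3 is nonzero.

    A run is a maximal stretch of consecutive alignment columns of one
    indel type: deletion (reference base, query gap) or insertion
    (reference gap, query base).  Columns gapped in both sequences belong
    to neither type.  Each out-of-frame run yields one call at its first
    column with detail 1 or 2.
    """
    ref = aln.sequences[aln.reference_id]
    first_col = aln.codon_columns[0][0]
    last_col = aln.codon_columns[-1][2]
    calls: list[DeleteriousCall] = []
    for sid in aln.query_ids:
        seq = aln.sequences[sid]
        run_type: str | None = None
        run_start = 0
        run_len = 0

        def close(out=calls, sid=sid):
            nonlocal run_type, run_len, run_start
            if run_type is not None and run_len % 3 != 0:
                out.append(
                    DeleteriousCall(
                        sequence_id=sid,
                        kind="frameshift",
                        column=run_start + 1,
                        codon=aln.codon_of_column(run_start),
                        detail=str(run_len % 3),
                    )
                )
            run_type, run_len = None, 0

        for col in range(first_col, last_col + 1):
            r, q = ref[col], seq[col]
            if r != "-" and q == "-":
                t = "del"
            elif r == "-" and q != "-":
                t = "ins"
            else:
                close()
                continue
            if t != run_type:
                close()
                run_type, run_start, run_len = t, col, 1
            else:
                run_len += 1
        close()
    return calls


def scan_alignment(aln: CodingAlignment) -> dict[str, list[DeleteriousCall]]:
    """All lesions per sequence id (frameshifts then premature stops,
    ordered by column)."""
    out: dict[str, list[DeleteriousCall]] = {sid: [] for sid in aln.query_ids}
    for call in detect_frameshifts(aln) + detect_premature_stops(aln):
        out[call.sequence_id].append(call)
    for sid in out:
        out[sid].sort(key=lambda c: (c.column, c.kind))
    return out


@dataclass
class SharedMutationReport:
    """Lesions identical in kind and position in both members of a pair."""

    pair: tuple[str, str]
    shared: list[tuple[DeleteriousCall, DeleteriousCall]] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def shared_deleterious(
    calls_by_sequence: dict[str, list[DeleteriousCall]],
    pairs: list[tuple[str, str]],
) -> list[SharedMutationReport]:
    """Match lesions between designated pairs (e.g. sympatric sister
    species): premature stops share on the reference codon index,
    frameshifts on start column and shift length."""
    reports = []
    for a, b in pairs:
        for sid in (a, b):
            if sid not in calls_by_sequence:
                raise ValueError(f"unknown sequence id in pair: {sid!r}")
        by_key_b = {}
        for call in calls_by_sequence[b]:
            by_key_b.setdefault(call.key(), call)
        rep = SharedMutationReport(pair=(a, b))
        seen = set()
        for call in calls_by_sequence[a]:
            k = call.key()
            if k in by_key_b and k not in seen:
                rep.shared.append((call, by_key_b[k]))
                seen.add(k)
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# I/O


def read_alignment_fasta(
    handle_or_text,
    reference_id: str | None = None,
    frame_offset: int = 0,
) -> CodingAlignment:
    """Read an aligned FASTA; the reference defaults to the first record."""
    if isinstance(handle_or_text, str):
        handle_or_text = io.StringIO(handle_or_text)
    records = list(SeqIO.parse(handle_or_text, "fasta"))
    if not records:
        raise ValueError("no sequences in FASTA input")
    seqs = {r.id: str(r.seq) for r in records}
    if len(seqs) != len(records):
        raise ValueError("duplicate sequence ids in FASTA input")
    return CodingAlignment(
        seqs, reference_id or records[0].id, frame_offset=frame_offset
    )


def calls_to_tsv(calls_by_sequence: dict[str, list[DeleteriousCall]]) -> str:
    lines = ["sequence\tkind\tcolumn\tcodon\tdetail\tpost_frameshift"]
    for sid in sorted(calls_by_sequence):
        for c in calls_by_sequence[sid]:
            lines.append(
                f"{c.sequence_id}\t{c.kind}\t{c.column}\t{c.codon}\t{c.detail}"
                f"\t{int(c.post_frameshift)}"
            )
    return "\n".join(lines) + "\n"


def shared_report_json(reports: list[SharedMutationReport]) -> str:
    payload = []
    for r in reports:
        payload.append(
            {
                "pair": list(r.pair),
                "n_shared": r.n_shared,
                "shared": [
                    {
                        "kind": a.kind,
                        "codon": a.codon,
                        "column": a.column,
                        "detail": a.detail,
                    }
                    for a, _ in r.shared
                ],
            }
        )
    return json.dumps(payload, indent=2, sort_keys=True)
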
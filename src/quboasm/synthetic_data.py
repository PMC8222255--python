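"""Synthetic inputs for the assembly pipeline.

Two generators cover everything downstream stages consume:

* short random nucleotide sequences fragmented into k-mers, screened so
  that each retained problem has a duplicate-free k-mer set (hence a
  Hamiltonian path exists in its overlap graph by construction), is not a
  bare chain, and is unique within the set;
* error-free fixed-length reads sampled uniformly from a (possibly
  circular) reference, emulating an idealised shotgun sequencing run.

All randomness flows through explicit integer seeds; identical seeds give
byte-identical FASTA output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

__all__ = [
    "ALPHABET",
    "SequenceRecord",
    "SyntheticProblem",
    "SyntheticProblemSet",
    "random_sequence",
    "kmerize",
    "generate_problem_set",
    "simulate_reads",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A labelled nucleotide string over {A, C, G, T}.

    The sequence is case-normalised to upper on construction; empty
    sequences or characters outside the 4-letter alphabet are rejected.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if set(seq) - set(ALPHABET):
            bad = sorted(set(seq) - set(ALPHABET))
            raise ValueError(f"record {self.id!r}: invalid characters {bad}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SyntheticProblem:
    """One assembly instance: a source sequence and its k-mer fragments."""

    source: SequenceRecord
    k: int
    reads: tuple[SequenceRecord, ...]


@dataclass
class SyntheticProblemSet:
    """A screened collection of synthetic assembly problems."""

    problems: list[SyntheticProblem]
    seed: int
    lengths: list[int]
    per_length: int
    k: int
    # generation diagnostics: candidates examined / rejected per reason
    stats: dict = field(default_factory=dict)
    complete: bool = True

    def by_length(self, length: int) -> list[SyntheticProblem]:
        return [p for p in self.problems if len(p.source) == length]


def random_sequence(length: int, rng_seed: int | np.random.Generator) -> SequenceRecord:
    """Draw a uniform i.i.d. nucleotide sequence of the given length."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    seq = "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])
    return SequenceRecord(id=f"rand_L{length}", seq=seq)


def kmerize(seq: SequenceRecord | str, k: int) -> list[str]:
    """Sliding-window substrings of length k, in order (duplicates kept)."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(s) < k:
        raise ValueError(f"sequence of length {len(s)} is shorter than k={k}")
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def _is_trivial_chain(kmers: Sequence[str], k: int) -> bool:
    """True when the k-mer overlap graph is a bare chain: its only edges are
    the consecutive ones, so no optimisation is needed to order it."""
    # local import: olc_graph imports nothing from here at module load time
    from .olc_graph import build_olc_graph

    if len(kmers) < 2:
        return True  # a single k-mer needs no ordering at all
    g = build_olc_graph(
        [SequenceRecord(f"kmer{i}", km) for i, km in enumerate(kmers)],
        min_overlap=k - 1,
        collapse_duplicates=True,
    )
    return g.M == g.N - 1


def generate_problem_set(
    lengths: Iterable[int],
    per_length: int,
    k: int,
    rng_seed: int,
    retry_cap: int = 1000,
) -> SyntheticProblemSet:
    """Sample random sequences per length and screen them into problems.

    A candidate sequence is retained when (i) its k-mer multiset has no
    duplicates, so a Hamiltonian path through the k-mer graph exists by
    construction, (ii) its overlap graph is not a bare chain (such graphs
    need no optimisation), and (iii) its sorted k-mer list has not been
    seen before (graph de-duplication).  Sampling continues until
    ``per_length`` problems are retained per length or ``retry_cap``
    candidates have been examined for that length; exhaustion yields a
    partial set flagged ``complete=False``.
    """
    lengths = list(lengths)
    if per_length < 0:
        raise ValueError("per_length must be >= 0")
    if any(L < k for L in lengths):
        raise ValueError(f"all lengths must be >= k={k}")
    rng = np.random.default_rng(rng_seed)
    problems: list[SyntheticProblem] = []
    seen_keys: set[tuple[str, ...]] = set()
    stats = {
        "examined": 0,
        "rejected_duplicate_kmers": 0,
        "rejected_trivial_chain": 0,
        "rejected_duplicate_problem": 0,
    }
    complete = True
    for L in lengths:
        kept = 0
        tries = 0
        while kept < per_length and tries < retry_cap:
            tries += 1
            stats["examined"] += 1
            cand = random_sequence(L, rng)
            kmers = kmerize(cand, k)
            if len(set(kmers)) != len(kmers):
                stats["rejected_duplicate_kmers"] += 1
                continue
            key = tuple(sorted(kmers))
            if key in seen_keys:
                stats["rejected_duplicate_problem"] += 1
                continue
            if _is_trivial_chain(kmers, k):
                stats["rejected_trivial_chain"] += 1
                continue
            seen_keys.add(key)
            source = SequenceRecord(id=f"L{L}_p{kept}", seq=cand.seq)
            reads = tuple(
                SequenceRecord(id=f"{source.id}_kmer{i}", seq=km)
                for i, km in enumerate(kmers)
            )
            problems.append(SyntheticProblem(source=source, k=k, reads=reads))
            kept += 1
        if kept < per_length:
            complete = False
    return SyntheticProblemSet(
        problems=problems,
        seed=rng_seed,
        lengths=lengths,
        per_length=per_length,
        k=k,
        stats=stats,
        complete=complete,
    )


def simulate_reads(
    reference: SequenceRecord,
    n_reads: int,
    read_length: int,
    circular: bool = False,
    rng_seed: int | np.random.Generator = 0,
) -> list[SequenceRecord]:
    """Sample error-free forward-strand reads at uniform start positions.

    On a circular reference, reads may wrap around the origin; on a linear
    reference the read length must not exceed the reference length.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    ref = reference.seq
    if read_length > len(ref):
        raise ValueError(
            f"read_length {read_length} exceeds reference length {len(ref)}"
        )
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if circular:
        starts = rng.integers(0, len(ref), size=n_reads)
        doubled = ref + ref
        return [
            SequenceRecord(id=f"read{i}", seq=doubled[s : s + read_length])
            for i, s in enumerate(starts)
        ]
    starts = rng.integers(0, len(ref) - read_length + 1, size=n_reads)
    return [
        SequenceRecord(id=f"read{i}", seq=ref[s : s + read_length])
        for i, s in enumerate(starts)
    ]


# ---------------------------------------------------------------------------
# FASTA / manifest I/O


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, 60-column wrapped."""
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_manifest(pset: SyntheticProblemSet, path: str | Path) -> None:
    """JSON manifest recording seeds, counts and rejection statistics."""
    manifest = {
        "seed": pset.seed,
        "lengths": pset.lengths,
        "per_length": pset.per_length,
        "k": pset.k,
        "n_problems": len(pset.problems),
        "complete": pset.complete,
        "stats": pset.stats,
        "problems": [
            {"id": p.source.id, "source": p.source.seq, "k": p.k, "n_reads": len(p.reads)}
            for p in pset.problems
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
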
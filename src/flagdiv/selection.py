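"""Selective-pressure curves: codon alignment and cumulative syn/nonsyn counts.

Coding sequences are aligned through their protein translations (so gaps
are whole codons), and each non-reference sequence is compared to a
reference codon by codon.  Synonymous and nonsynonymous differences are
counted by Nei–Gojobori pathway averaging: for a codon pair differing at
``d`` positions, every minimal mutational pathway (each ordering of the
``d`` single-base steps) is enumerated, pathways crossing a stop codon are
excluded, and the synonymous/nonsynonymous step counts are averaged over
the remaining pathways.  Each pathway contributes syn + nonsyn = d, so the
average also sums to the Hamming distance.  Running these counts from the
N to the C terminus gives cumulative curves whose slopes localise
selection: synonymous-dominated slopes in the conserved terminal regions,
nonsynonymous-dominated slopes in the hypervariable middle.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .sequence_model import SequenceRecord, read_fasta, translate, write_fasta

GAP_CODON = "---"
_STOPS = frozenset(standard_dna_table.stop_codons)
_FORWARD = dict(standard_dna_table.forward_table)


def _aa(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _FORWARD.get(codon)


@lru_cache(maxsize=8192)
def count_syn_nonsyn(codon_a: str, codon_b: str,
                     include_stop_paths: bool = False) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) counts between two codons.

    Averages over all orderings of the differing positions; pathways whose
    intermediate codons are stops are excluded unless every pathway crosses
    a stop, in which case all pathways are used (documented fallback).
    Codons containing N contribute (0, 0).  syn + nonsyn always equals the
    Hamming distance of the codons.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise ValueError("codons must be length 3")
    if set(codon_a + codon_b) - set("ACGT"):
        return 0.0, 0.0  # ambiguous or gapped codon, flagged upstream
    if codon_a in _STOPS or codon_b in _STOPS:
        raise ValueError("endpoint codons must be sense codons")
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = list(codon_a)
        syn = nonsyn = 0
        for pos in order:
            before = "".join(cur)
            cur[pos] = codon_b[pos]
            after = "".join(cur)
            if after in _STOPS and not include_stop_paths:
                return None
            aa_before, aa_after = _aa(before), _aa(after)
            if (aa_before is not None and aa_after is not None
                    and aa_before == aa_after):
                syn += 1
            else:
                nonsyn += 1
        return float(syn), float(nonsyn)

    results = [r for r in (walk(o) for o in permutations(diffs)) if r is not None]
    if not results:
        return count_syn_nonsyn(codon_a, codon_b, include_stop_paths=True)
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


@lru_cache(maxsize=128)
def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Nei–Gojobori potential synonymous/nonsynonymous site counts of a codon.

    Each position contributes the fraction of its possible base changes
    that are synonymous; changes producing stop codons are excluded from
    the denominator.  Emitted alongside the raw cumulative counts for
    users who want site-normalised rates.
    """
    codon = codon.upper()
    if set(codon) - set("ACGT") or codon in _STOPS:
        return 0.0, 0.0
    syn_sites = 0.0
    total_sites = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        syn_frac = 0.0
        n_valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in _STOPS:
                continue
            n_valid += 1
            if _aa(alt) == aa0:
                syn_frac += 1.0
        if n_valid:
            syn_sites += syn_frac / n_valid
            total_sites += 1.0
    return syn_sites, total_sites - syn_sites


@dataclass
class CodonAlignment:
    """Codon-columned multiple alignment of coding sequences.

    ``rows`` maps sequence id to its list of cells, each a codon triplet or
    the gap codon ``---``; all rows have the same number of columns.
    ``trailing`` holds any trailing stop codon removed before alignment so
    the original CDS can be restored exactly.
    """

    ids: list[str]
    rows: dict[str, list[str]]
    trailing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(cells) for cells in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("all rows must have the same column count")
        for rid, cells in self.rows.items():
            for cell in cells:
                if cell != GAP_CODON and (len(cell) != 3
                                          or set(cell) - set("ACGTN")):
                    raise ValueError(f"row {rid!r}: bad cell {cell!r}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, rid: str) -> str:
        """Original CDS of one row (gaps stripped, trailing stop restored)."""
        core = "".join(c for c in self.rows[rid] if c != GAP_CODON)
        return core + self.trailing.get(rid, "")

    @classmethod
    def from_aligned_strings(cls, aligned: dict[str, str]) -> "CodonAlignment":
        """Build from pre-aligned DNA strings (gaps ``-``, length % 3 == 0)."""
        rows = {}
        for rid, seq in aligned.items():
            seq = seq.upper()
            if len(seq) % 3:
                raise ValueError(f"{rid}: aligned length not divisible by 3")
            cells = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            cells = [GAP_CODON if set(c) == {"-"} else c for c in cells]
            if any("-" in c and c != GAP_CODON for c in cells):
                raise ValueError(f"{rid}: gaps are not whole-codon aligned")
            rows[rid] = cells
        return cls(ids=list(aligned), rows=rows)


def _run_mafft(records: list[SequenceRecord]) -> dict[str, str]:
    """Protein multiple alignment via MAFFT; returns id -> aligned string."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(records, inp)
        proc = subprocess.run(["mafft", "--quiet", "--auto", str(inp)],
                              capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip().upper()
    return out


def codon_align(cds_list: list[SequenceRecord]) -> CodonAlignment:
    """Align coding sequences through their translations (whole-codon gaps).

    Each CDS is translated (untranslatable input raises an error naming the
    record), the proteins are multiple-aligned, and protein gaps are
    threaded back onto the DNA as one gap codon per gap residue.  Stripping
    gaps restores every input exactly.
    """
    if len(cds_list) < 2:
        raise ValueError("codon alignment needs at least 2 sequences")
    proteins = []
    codons_by_id: dict[str, list[str]] = {}
    trailing: dict[str, str] = {}
    for rec in cds_list:
        prot = translate(rec)
        proteins.append(prot)
        codons = [rec.residues[i:i + 3] for i in range(0, len(rec.residues), 3)]
        if len(codons) == len(prot.residues) + 1:   # trailing stop dropped
            trailing[rec.id] = codons[-1]
            codons = codons[:-1]
        codons_by_id[rec.id] = codons
    if len(proteins) == 2 and proteins[0].residues == proteins[1].residues:
        aligned = {p.id: p.residues for p in proteins}  # trivial, skip aligner
    else:
        aligned = _run_mafft(proteins)
    rows: dict[str, list[str]] = {}
    for rec in cds_list:
        aln = aligned[rec.id]
        codons = iter(codons_by_id[rec.id])
        rows[rec.id] = [GAP_CODON if ch == "-" else next(codons) for ch in aln]
    return CodonAlignment(ids=[r.id for r in cds_list], rows=rows,
                          trailing=trailing)


@dataclass
class CumulativeCurves:
    """Cumulative syn/nonsyn/indel series along reference codon positions.

    All three series are non-decreasing; positions are 1-based reference
    codon indices from the N terminus.
    """

    reference_id: str
    positions: np.ndarray
    cum_syn: np.ndarray
    cum_nonsyn: np.ndarray
    cum_indel: np.ndarray
    mode: str = "mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "cum_syn": self.cum_syn,
            "cum_nonsyn": self.cum_nonsyn,
            "cum_indel": self.cum_indel,
        })


def _indel_openings(ref_cells: list[str], row_cells: list[str],
                    pos_index: list[int]) -> np.ndarray:
    """Per-reference-position gap-opening counts for one row.

    A deletion (row gap at a reference column) is charged to that
    position; an insertion (row residue at a reference-gap column) is
    charged to the preceding reference position (or the first).
    ``pos_index[c]`` is the reference-position index at or before column c.
    """
    n_pos = max(pos_index) + 1
    inc = np.zeros(n_pos)
    in_del = False
    in_ins = False
    for c, (ref_cell, row_cell) in enumerate(zip(ref_cells, row_cells)):
        if ref_cell != GAP_CODON:
            if row_cell == GAP_CODON:
                if not in_del:
                    inc[pos_index[c]] += 1
                in_del = True
            else:
                in_del = False
            in_ins = False
        else:
            if row_cell != GAP_CODON:
                if not in_ins:
                    inc[pos_index[c]] += 1
                in_ins = True
            else:
                in_ins = False
    return inc


def cumulative_curves(alignment: CodonAlignment,
                      reference_id: str | None = None,
                      rng_seed: int | None = None,
                      mode: str = "mean") -> CumulativeCurves:
    """Cumulative synonymous/nonsynonymous/indel curves against a reference.

    At each reference codon position (N to C, reference coordinates) the
    mean over all non-reference rows of the pathway-averaged counts is
    added to the running totals (``mode="sum"`` accumulates row sums
    instead); the indel series counts rows opening a gap at that position.
    With no ``reference_id`` the reference is drawn uniformly using
    ``rng_seed``, mirroring a randomly selected reference sequence.
    """
    if len(alignment.ids) < 2:
        raise ValueError("need at least 2 rows")
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    if reference_id is None:
        rng = np.random.default_rng(rng_seed)
        reference_id = alignment.ids[int(rng.integers(len(alignment.ids)))]
    if reference_id not in alignment.rows:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    others = [i for i in alignment.ids if i != reference_id]
    ref_cells = alignment.rows[reference_id]
    n_rows = len(others)

    ref_cols = [c for c, cell in enumerate(ref_cells) if cell != GAP_CODON]
    if not ref_cols:
        raise ValueError("reference row is all gaps")
    pos_index = []
    cur = 0
    for c in range(len(ref_cells)):
        if ref_cells[c] != GAP_CODON and c > ref_cols[0]:
            cur += 1
        pos_index.append(cur if c >= ref_cols[0] else 0)

    n_pos = len(ref_cols)
    syn_inc = np.zeros(n_pos)
    nonsyn_inc = np.zeros(n_pos)
    indel_inc = np.zeros(n_pos)
    for rid in others:
        cells = alignment.rows[rid]
        for p, col in enumerate(ref_cols):
            cell = cells[col]
            if cell != GAP_CODON:
                s, ns = count_syn_nonsyn(ref_cells[col], cell)
                syn_inc[p] += s
                nonsyn_inc[p] += ns
        indel_inc += _indel_openings(ref_cells, cells, pos_index)
    if mode == "mean":
        syn_inc /= n_rows
        nonsyn_inc /= n_rows
    return CumulativeCurves(
        reference_id=reference_id,
        positions=np.arange(1, n_pos + 1),
        cum_syn=np.cumsum(syn_inc),
        cum_nonsyn=np.cumsum(nonsyn_inc),
        cum_indel=np.cumsum(indel_inc),
        mode=mode,
    )


def write_curves(curves: CumulativeCurves, path) -> None:
    curves.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_cds_fasta(path) -> list[SequenceRecord]:
    return read_fasta(path, kind="dna")
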
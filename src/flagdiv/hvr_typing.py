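"""Hypervariable-region (HVR) typing: region partition, forms, isoforms, NJ trees.

A flagellin gene is cut into a 5' conserved region (570 bp), a middle
variable region, and a 3' conserved region (300 bp); in protein mode the
same cut is 190 and 100 residues.  Variable regions fall into *forms* —
classes so divergent that no meaningful alignment exists between classes —
and, within a form, *isoforms* differing by SNP-level variation.  Forms are
the connected components of a thresholded-alignability relation (single
linkage, honouring the "no alignment with any other" definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairwise_align import DEFAULT_SCHEME, ScoringScheme, align_local
from .sequence_model import SequenceRecord

CONSERVED5_BP = 570
CONSERVED3_BP = 300
CONSERVED5_AA = CONSERVED5_BP // 3   # 190
CONSERVED3_AA = CONSERVED3_BP // 3   # 100

DEFAULT_MIN_IDENTITY = 0.35
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class RegionPartition:
    """Conserved/variable/conserved split of one sequence (0-based, half-open)."""

    record_id: str
    mode: str                     # "dna" or "protein"
    conserved5: str
    variable: str
    conserved3: str

    @property
    def boundaries(self) -> tuple[int, int]:
        return len(self.conserved5), len(self.conserved5) + len(self.variable)

    def restore(self) -> str:
        return self.conserved5 + self.variable + self.conserved3


@dataclass
class HvrIsoform:
    isoform_id: str
    sequence: str
    member_ids: list[str] = field(default_factory=list)


@dataclass
class HvrForm:
    form_id: str
    representative: str
    isoforms: list[HvrIsoform] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return sum(len(iso.member_ids) for iso in self.isoforms)


def partition_gene(record: SequenceRecord) -> RegionPartition:
    """Cut one sequence into conserved 5'/N, variable middle, conserved 3'/C.

    DNA: first 570 bp and last 300 bp conserved; protein: first 190 aa and
    last 100 aa.  The sequence must be long enough to leave a non-empty
    variable region.
    """
    if record.kind == "dna":
        lo, hi = CONSERVED5_BP, CONSERVED3_BP
    else:
        lo, hi = CONSERVED5_AA, CONSERVED3_AA
    seq = record.residues
    if len(seq) <= lo + hi:
        raise ValueError(
            f"record {record.id!r}: length {len(seq)} leaves no variable "
            f"region (minimum {lo + hi + 1} for kind={record.kind!r})"
        )
    return RegionPartition(
        record_id=record.id, mode=record.kind,
        conserved5=seq[:lo], variable=seq[lo:len(seq) - hi],
        conserved3=seq[len(seq) - hi:],
    )


def alignable(va: str, vb: str,
              min_identity: float = DEFAULT_MIN_IDENTITY,
              min_coverage: float = DEFAULT_MIN_COVERAGE,
              scheme: ScoringScheme = DEFAULT_SCHEME) -> bool:
    """Thresholded local-alignment predicate between two variable regions.

    True iff identity over aligned columns reaches ``min_identity`` and the
    aligned span covers at least ``min_coverage`` of the shorter region.
    Symmetric.  "No alignment" between HVR forms means this is False for
    every cross-form pair.
    """
    if not va or not vb:
        raise ValueError("empty variable region")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    res = align_local(va, vb, scheme)
    if not res.path:
        return False
    cov = res.query_cov if len(va) <= len(vb) else res.subject_cov
    return res.identity >= min_identity and cov >= min_coverage


def assign_hvr_forms(regions: dict[str, list[str]],
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_coverage: float = DEFAULT_MIN_COVERAGE,
                     scheme: ScoringScheme = DEFAULT_SCHEME) -> list[HvrForm]:
    """Group variable regions into forms (single linkage) and isoforms.

    ``regions`` maps each distinct variable-region string to the record ids
    carrying it.  Forms are connected components of the alignable relation
    over distinct strings; isoforms are the distinct strings within a form.
    Form ids are assigned by descending member count, ties by
    lexicographically smallest representative; the output is independent of
    input order.
    """
    keys = sorted(regions)
    n = len(keys)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if alignable(keys[i], keys[j], min_identity, min_coverage, scheme):
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(keys[i])

    forms: list[HvrForm] = []
    for seqs in groups.values():
        isoforms = [HvrIsoform(isoform_id="", sequence=s,
                               member_ids=sorted(regions[s])) for s in seqs]
        isoforms.sort(key=lambda iso: (-len(iso.member_ids), iso.sequence))
        rep = isoforms[0].sequence
        forms.append(HvrForm(form_id="", representative=rep, isoforms=isoforms))
    forms.sort(key=lambda f: (-f.n_members, f.representative))
    for fi, form in enumerate(forms, start=1):
        form.form_id = f"F{fi:03d}"
        for ii, iso in enumerate(form.isoforms, start=1):
            iso.isoform_id = f"{form.form_id}.{ii}"
    return forms


def score_distance_matrix(seqs: dict[str, str],
                          scheme: ScoringScheme = DEFAULT_SCHEME
                          ) -> tuple[list[str], np.ndarray]:
    """Pairwise distances d = 1 - raw(a,b)/min(raw self-scores), clipped to [0,1].

    The normalised-score transform turns pairwise alignment scores into the
    distance matrix the NJ tree is built from.
    """
    ids = sorted(seqs)
    selfscore = {i: align_local(seqs[i], seqs[i], scheme).raw_score for i in ids}
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(selfscore[ids[i]], selfscore[ids[j]])
            raw = align_local(seqs[ids[i]], seqs[ids[j]], scheme).raw_score
            d = 1.0 - raw / denom if denom > 0 else 1.0
            mat[i, j] = mat[j, i] = float(min(max(d, 0.0), 1.0))
    return ids, mat


def nj_tree(labels: list[str], distances: np.ndarray) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    Deterministic: ties in the Q criterion are broken by the smallest
    (lexicographic) pair of subtree labels; negative branch lengths are
    clamped to zero.  Requires at least 3 taxa and a symmetric,
    zero-diagonal distance matrix.
    """
    d = np.asarray(distances, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    # active nodes: (sort_key, newick fragment)
    nodes = [(lab, lab) for lab in labels]
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = d[i, j]
    active = list(range(n))
    next_idx = n

    def dget(a: int, b: int) -> float:
        return dist[frozenset((a, b))]

    node_info = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dget(a, b) - r[a] - r[b]
                key_pair = tuple(sorted((node_info[a][0], node_info[b][0])))
                cand = (q, key_pair, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        dab = dget(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        ka, nwk_a = node_info[a]
        kb, nwk_b = node_info[b]
        new_nwk = f"({nwk_a}:{la:.6f},{nwk_b}:{lb:.6f})"
        u = next_idx
        next_idx += 1
        node_info[u] = (min(ka, kb), new_nwk)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dget(a, c) + dget(b, c) - dab)
            dist[frozenset((u, c))] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active, key=lambda x: node_info[x][0])
    dab, dac, dbc = dget(a, b), dget(a, c), dget(b, c)
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    return (f"({node_info[a][1]}:{la:.6f},{node_info[b][1]}:{lb:.6f},"
            f"{node_info[c][1]}:{lc:.6f});")


def write_form_table(forms: list[HvrForm],
                     partitions: dict[str, RegionPartition], path) -> None:
    """TSV: record id, form, isoform, and variable-region coordinates."""
    with open(path, "w") as fh:
        fh.write("record_id\tform_id\tisoform_id\tvar_start\tvar_end\n")
        for form in forms:
            for iso in form.isoforms:
                for rid in iso.member_ids:
                    part = partitions.get(rid)
                    lo, hi = part.boundaries if part else ("", "")
                    fh.write(f"{rid}\t{form.form_id}\t{iso.isoform_id}\t"
                             f"{lo}\t{hi}\n")
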
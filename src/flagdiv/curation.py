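"""Database-curation funnel: domain filtering, homolog fishing, FlgL removal.

Flagellin curation keeps a protein only if it carries both bacterial
conserved terminal domains (the D0/D1 N- and C-terminal regions) or the
single archaeal domain.  The flagellar junction protein FlgL shares the
conserved domains and is removed by a two-profile likelihood-ratio: a
candidate scoring higher under the FlgL discriminant profile than under the
flagellin discriminant profile is rejected as FlgL-like.

Domain presence is detected by sliding-window position-specific scoring
matrices (PSSMs).  The detector is deliberately pluggable: models can be
built from any aligned seed set (:meth:`DomainModel.from_sequences`) or
loaded from TSV, so an HMM-based scanner can be swapped in for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairwise_align import DEFAULT_SCHEME, ScoringScheme, bsr
from .sequence_model import SequenceRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# recognised model roles
FLAG_N = "FLAG_N"
FLAG_C = "FLAG_C"
ARCH_FLAG = "ARCH_FLAG"
FLGL_DISCRIM = "FLGL_DISCRIM"
FLAGELLIN_DISCRIM = "FLAGELLIN_DISCRIM"

BACTERIAL = "bacterial_flagellin"
ARCHAEAL = "archaeal_flagellin"
FLGL_LIKE = "flgl_like"
NON_FLAGELLIN = "non_flagellin"


@dataclass
class DomainModel:
    """Sliding-window PSSM for one conserved domain.

    ``pssm`` has one row per position and one column per amino acid in
    :data:`AA_ORDER`, in bits (log2 odds against a uniform background).
    ``expected_terminus`` constrains where the best window midpoint may
    fall: the N-terminal half, the C-terminal half, or anywhere.
    """

    domain_id: str
    pssm: np.ndarray
    min_score: float
    expected_terminus: str = "any"

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
            raise ValueError("pssm must be positions x 20 amino acids")
        if self.pssm.shape[0] < 5:
            raise ValueError("pssm must have at least 5 positions")
        if not np.isfinite(self.min_score):
            raise ValueError("min_score must be finite")
        if self.expected_terminus not in ("N", "C", "any"):
            raise ValueError("expected_terminus must be 'N', 'C' or 'any'")

    def __len__(self) -> int:
        return self.pssm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.pssm.argmax(axis=1))

    @property
    def consensus_score(self) -> float:
        """Sum of column maxima — the best achievable window score."""
        return float(self.pssm.max(axis=1).sum())

    @classmethod
    def from_sequences(cls, domain_id: str, seqs: list[str],
                       expected_terminus: str = "any",
                       min_score: float | None = None,
                       pseudocount: float = 1.0) -> "DomainModel":
        """Build a log-odds PSSM from equal-length ungapped seed sequences.

        Column probabilities use Dirichlet pseudocounts against a uniform
        background.  When ``min_score`` is omitted it defaults to half the
        lowest seed-sequence score under the finished model, so every seed
        family member passes with margin (the same spirit as curated
        profile gathering thresholds).
        """
        if not seqs:
            raise ValueError("need at least one seed sequence")
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("seed sequences must be equal length (ungapped)")
        counts = np.full((length, 20), pseudocount / 20.0)
        for s in seqs:
            for pos, aa in enumerate(s):
                if aa in _AA_INDEX:  # X contributes nothing
                    counts[pos, _AA_INDEX[aa]] += 1.0
        probs = counts / counts.sum(axis=1, keepdims=True)
        pssm = np.log2(probs / 0.05)
        model = cls(domain_id=domain_id, pssm=pssm, min_score=0.0,
                    expected_terminus=expected_terminus)
        if min_score is None:
            seed_scores = [model.best_window(s)[0] for s in seqs]
            min_score = 0.5 * min(seed_scores)
        model.min_score = float(min_score)
        return model

    def best_window(self, protein: str) -> tuple[float, int]:
        """(best window score, window start); -inf if protein shorter than model."""
        w = len(self)
        if len(protein) < w:
            return float("-inf"), -1
        idx = np.array([_AA_INDEX.get(a, -1) for a in protein])
        best = float("-inf")
        best_start = -1
        # unknown residues (X) contribute zero to any window
        col = np.where(idx >= 0, idx, 0)
        valid = idx >= 0
        n_windows = len(protein) - w + 1
        rows = np.arange(w)
        for start in range(n_windows):
            seg_col = col[start:start + w]
            seg_valid = valid[start:start + w]
            s = float(np.sum(self.pssm[rows, seg_col] * seg_valid))
            if s > best:
                best, best_start = s, start
        return best, best_start


@dataclass(frozen=True)
class DomainHit:
    domain_id: str
    score: float
    start: int
    end: int


@dataclass
class CurationReport:
    """Stage-tagged accounting of every input record.

    ``accepted`` maps record id -> category; ``rejected`` lists
    (record id, stage, reason); ``fished`` lists pool ids added by homolog
    fishing (these also appear in ``accepted``).
    """

    accepted: dict[str, str] = field(default_factory=dict)
    rejected: list[tuple[str, str, str]] = field(default_factory=list)
    fished: list[str] = field(default_factory=list)


def scan_domains(record: SequenceRecord,
                 models: list[DomainModel]) -> list[DomainHit]:
    """Best-window PSSM scan of one protein against each domain model.

    A model yields a hit iff its best window scores at least ``min_score``
    and the window midpoint lies in the expected terminal half.  A protein
    shorter than a model simply yields no hit for it.
    """
    if record.kind != "protein":
        raise ValueError(f"record {record.id!r} is not a protein")
    hits: list[DomainHit] = []
    for model in models:
        score, start = model.best_window(record.residues)
        if start < 0 or score < model.min_score:
            continue
        end = start + len(model)
        mid = (start + end) / 2.0
        half = len(record.residues) / 2.0
        if model.expected_terminus == "N" and mid > half:
            continue
        if model.expected_terminus == "C" and mid < half:
            continue
        hits.append(DomainHit(model.domain_id, score, start, end))
    return hits


def classify_flagellin(hits: list[DomainHit], flgl_score: float,
                       flagellin_score: float) -> str:
    """Apply the domain-presence and FlgL-discriminant rules.

    bacterial iff both terminal domains hit and the flagellin discriminant
    score is at least the FlgL score (tie goes to flagellin); flgl_like iff
    both hit but FlgL scores higher; archaeal iff the archaeal domain hits
    and the bacterial pair does not; otherwise non-flagellin.
    """
    ids = {h.domain_id for h in hits}
    both_bacterial = FLAG_N in ids and FLAG_C in ids
    if both_bacterial:
        return BACTERIAL if flagellin_score >= flgl_score else FLGL_LIKE
    if ARCH_FLAG in ids:
        return ARCHAEAL
    return NON_FLAGELLIN


def _discriminant_scores(record: SequenceRecord,
                         models: list[DomainModel],
                         hits: list[DomainHit]) -> tuple[float, float]:
    """(flagellin_score, flgl_score) for the likelihood-ratio decision.

    Discriminant profiles are scored by best window with no threshold.
    Without an explicit flagellin discriminant the summed terminal-domain
    hit scores stand in; without an FlgL discriminant the FlgL score is
    -inf (nothing is ever called FlgL-like).
    """
    flag = None
    flgl = float("-inf")
    for model in models:
        if model.domain_id == FLAGELLIN_DISCRIM:
            flag, _ = model.best_window(record.residues)
        elif model.domain_id == FLGL_DISCRIM:
            flgl, _ = model.best_window(record.residues)
    if flag is None:
        flag = sum(h.score for h in hits if h.domain_id in (FLAG_N, FLAG_C))
    return flag, flgl


def classify_record(record: SequenceRecord,
                    models: list[DomainModel]) -> str:
    """Scan and classify one protein in a single call."""
    scan_models = [m for m in models
                   if m.domain_id in (FLAG_N, FLAG_C, ARCH_FLAG)]
    hits = scan_domains(record, scan_models)
    flag, flgl = _discriminant_scores(record, models, hits)
    return classify_flagellin(hits, flgl_score=flgl, flagellin_score=flag)


def fish_homologs(seeds: list[SequenceRecord], pool: list[SequenceRecord],
                  min_bsr: float = 0.4,
                  scheme: ScoringScheme = DEFAULT_SCHEME) -> list[SequenceRecord]:
    """Pull pool members whose best BSR against any seed reaches ``min_bsr``.

    Mirrors the seed-based search that recruits flagellin-like sequences
    missed by annotation; fished records must still pass the domain re-scan
    inside :func:`curate` before acceptance.
    """
    if not seeds:
        raise ValueError("fishing requires at least one seed sequence")
    if not 0.0 < min_bsr <= 1.0:
        raise ValueError("min_bsr must be in (0, 1]")
    out: list[SequenceRecord] = []
    for cand in pool:
        for seed in seeds:
            if bsr(cand.residues, seed.residues, scheme) >= min_bsr:
                out.append(cand)
                break
    return out


def curate(records: list[SequenceRecord], models: list[DomainModel],
           exclusion_ids: set[str] | None = None,
           pool: list[SequenceRecord] | None = None,
           min_bsr: float = 0.4,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> CurationReport:
    """Run the full curation funnel and account for every input id.

    Stages, in order: domain filter -> homolog fishing from ``pool``
    (optional; fished records are re-scanned before acceptance) -> FlgL
    removal -> exclusion-list removal.
    """
    exclusion_ids = exclusion_ids or set()
    report = CurationReport()

    def place(rec: SequenceRecord, fished: bool) -> None:
        category = classify_record(rec, models)
        if category in (BACTERIAL, ARCHAEAL):
            if rec.id in exclusion_ids:
                report.rejected.append((rec.id, "exclusion_list", "listed"))
            else:
                report.accepted[rec.id] = category
                if fished:
                    report.fished.append(rec.id)
        elif category == FLGL_LIKE:
            report.rejected.append(
                (rec.id, "flgl_filter", "FlgL discriminant scored higher"))
        else:
            report.rejected.append(
                (rec.id, "domain_filter", "required conserved domains absent"))

    for rec in records:
        place(rec, fished=False)

    if pool:
        seeds = [rec for rec in records if rec.id in report.accepted]
        if seeds:
            seen = {rec.id for rec in records}
            candidates = [rec for rec in pool if rec.id not in seen]
            for rec in fish_homologs(seeds, candidates, min_bsr, scheme):
                place(rec, fished=True)
    return report


def write_pssm(model: DomainModel, path) -> None:
    """TSV dump: rows = positions, columns = amino acids, values in bits."""
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(AA_ORDER) + "\n")
        fh.write(f"#domain_id={model.domain_id}\tmin_score={model.min_score}"
                 f"\texpected_terminus={model.expected_terminus}\n")
        for i, row in enumerate(model.pssm):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.5f}" for v in row) + "\n")


def read_pssm(path) -> DomainModel:
    meta = {"domain_id": "FLAG_N", "min_score": "0", "expected_terminus": "any"}
    rows = []
    with open(path) as fh:
        header = fh.readline()
        cols = header.strip().split("\t")[1:]
        for line in fh:
            if line.startswith("#"):
                for kv in line[1:].strip().split("\t"):
                    k, _, v = kv.partition("=")
                    meta[k] = v
                continue
            vals = line.strip().split("\t")
            if len(vals) < 21:
                continue
            by_aa = dict(zip(cols, map(float, vals[1:])))
            rows.append([by_aa[a] for a in AA_ORDER])
    return DomainModel(domain_id=meta["domain_id"], pssm=np.array(rows),
                       min_score=float(meta["min_score"]),
                       expected_terminus=meta["expected_terminus"])
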
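"""Position-weight-matrix scanning of promoter sequences.

Transcription-factor binding motifs are represented as position frequency
matrices (PFMs) in JASPAR text format.  Each motif is converted to a log-odds
score matrix against a background base composition and slid along both strands
of every 1 kb upstream promoter region; windows scoring at least a relative
fraction (default 0.80) of the motif's maximum achievable score are called
binding sites.  The result is the genes x motifs site-count matrix ``N`` that
the motif-activity regression consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .errors import InputError

logger = logging.getLogger("germnet.motifscan")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: uniform background over A, C, G, T
UNIFORM_BG = np.full(4, 0.25)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as integers 0..3, with 4 for N/other."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class MotifModel:
    """A binding motif: id, TF name(s), and a 4 x width count matrix.

    Rows of ``counts`` follow A, C, G, T order.  Dimer motifs keep their
    composite name verbatim (e.g. ``Fos::Jun``); :attr:`tf_genes` splits it
    into the constituent gene symbols.
    """

    motif_id: str
    name: str
    counts: np.ndarray
    rel_score_threshold: float = 0.8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise InputError(
                f"motif {self.motif_id}: PFM must be 4 x width, got shape "
                f"{self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise InputError(f"motif {self.motif_id}: negative PFM counts")
        totals = self.counts.sum(axis=0)
        if np.any(totals <= 0):
            raise InputError(
                f"motif {self.motif_id}: column with non-positive total"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def tf_genes(self) -> list[str]:
        return self.name.split("::")

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


def read_jaspar(path) -> list[MotifModel]:
    """Parse a JASPAR PFM file (``>ID NAME`` headers, four base rows)."""
    with open(path) as handle:
        try:
            parsed = list(bio_motifs.parse(handle, "jaspar"))
        except Exception as exc:  # ragged rows, garbage values
            raise InputError(f"cannot parse JASPAR file {path}: {exc}") from exc
    models = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        models.append(MotifModel(motif_id=m.matrix_id or m.name, name=m.name,
                                 counts=counts))
    if not models:
        raise InputError(f"no motifs found in {path}")
    logger.info("read %d motifs from %s", len(models), path)
    return models


def write_jaspar(motifs: list[MotifModel], path) -> None:
    """Write motifs in JASPAR PFM text format."""
    with open(path, "w") as handle:
        for m in motifs:
            handle.write(f">{m.motif_id} {m.name}\n")
            for b, row in zip(BASES, m.counts):
                vals = " ".join(f"{v:g}" for v in row)
                handle.write(f"{b} [ {vals} ]\n")


def log_odds(motif: MotifModel, background: np.ndarray | None = None,
             pseudocount: float = 0.8) -> np.ndarray:
    """Log2-odds score matrix of a motif against a background composition.

    score[b, j] = log2( (count[b,j] + pc*bg[b]) / (total_j + pc) / bg[b] ).
    The pseudocount is distributed according to the background so every
    entry is finite.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise InputError("background must be 4 positive probabilities summing to 1")
    totals = motif.counts.sum(axis=0)
    probs = (motif.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return np.log2(probs / bg[:, None])


def max_achievable_score(lom: np.ndarray) -> float:
    return float(lom.max(axis=0).sum())


def scan(sequence: str, motif: MotifModel, rel_score: float | None = None,
         background: np.ndarray | None = None,
         pseudocount: float = 0.8) -> int:
    """Count binding sites of ``motif`` on both strands of ``sequence``.

    A window counts as a site when its log-odds score is >= rel_score times
    the maximum achievable score.  Overlapping windows all count; windows
    containing N are skipped.  Strand-symmetric: scanning the reverse
    complement yields the same count.
    """
    counts = scan_batch({"_": sequence}, [motif], rel_score=rel_score,
                        background=background, pseudocount=pseudocount)
    return int(counts[0, 0])


def scan_batch(promoters: dict[str, str], motifs: list[MotifModel],
               rel_score: float | None = None,
               background: np.ndarray | None = None,
               pseudocount: float = 0.8) -> np.ndarray:
    """Site counts for every promoter x motif pair (vectorized scanner)."""
    encoded = {g: encode_sequence(s) for g, s in promoters.items()}
    out = np.zeros((len(promoters), len(motifs)), dtype=int)
    for j, motif in enumerate(motifs):
        lom = log_odds(motif, background=background, pseudocount=pseudocount)
        thr = (motif.rel_score_threshold if rel_score is None else rel_score)
        cutoff = thr * max_achievable_score(lom)
        # scoring the reverse strand == scoring with the reverse-complement
        # matrix on the forward encoding
        lom_rc = lom[::-1, ::-1]
        w = motif.width
        for i, (gene, enc) in enumerate(encoded.items()):
            if enc.size < w:
                warnings.warn(
                    f"promoter {gene} shorter than motif {motif.motif_id}; "
                    "count 0", stacklevel=2)
                continue
            out[i, j] = _count_sites(enc, lom, lom_rc, cutoff)
    return out


def _count_sites(enc: np.ndarray, lom: np.ndarray, lom_rc: np.ndarray,
                 cutoff: float) -> int:
    w = lom.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = ~(windows == 4).any(axis=1)
    if not valid.any():
        return 0
    wins = windows[valid].astype(np.intp)
    cols = np.arange(w)
    fwd = lom[wins, cols].sum(axis=1)
    rev = lom_rc[wins, cols].sum(axis=1)
    return int(np.count_nonzero(fwd >= cutoff) + np.count_nonzero(rev >= cutoff))


@dataclass
class SiteCountMatrix:
    """Genes x motifs matrix N of predicted binding-site counts."""

    N: pd.DataFrame  # index = gene ids, columns = motif ids

    def __post_init__(self) -> None:
        if (self.N.values < 0).any():
            raise InputError("site counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.N.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.N.columns)

    def binarized(self) -> "SiteCountMatrix":
        return SiteCountMatrix((self.N > 0).astype(int))

    def to_tsv(self, path) -> None:
        self.N.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "SiteCountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def build_site_matrix(promoters: dict[str, str], motifs: list[MotifModel],
                      rel_score: float | None = None,
                      gene_ids: list[str] | None = None,
                      binarize: bool = False,
                      missing_promoter: str = "zeros",
                      max_promoter_length: int = 1000) -> SiteCountMatrix:
    """Scan every promoter with every motif and assemble N.

    Promoters longer than ``max_promoter_length`` are trimmed to their
    proximal (3') end with a warning.  Genes requested via ``gene_ids`` but
    missing a promoter get a zero row (``missing_promoter='zeros'``) or raise
    (``'error'``).
    """
    trimmed = {}
    for g, seq in promoters.items():
        if len(seq) > max_promoter_length:
            warnings.warn(
                f"promoter {g} longer than {max_promoter_length} bp; trimmed "
                "to the proximal end", stacklevel=2)
            seq = seq[-max_promoter_length:]
        trimmed[g] = seq
    counts = scan_batch(trimmed, motifs, rel_score=rel_score)
    df = pd.DataFrame(counts, index=list(trimmed), columns=[m.motif_id for m in motifs])
    if gene_ids is not None:
        missing = [g for g in gene_ids if g not in df.index]
        if missing:
            if missing_promoter == "error":
                raise InputError(f"genes without promoters: {missing[:10]}")
            logger.warning("%d genes without promoter; zero rows", len(missing))
        df = df.reindex(gene_ids, fill_value=0)
    if binarize:
        df = (df > 0).astype(int)
    logger.info("site matrix: %d genes x %d motifs, %d total sites",
                df.shape[0], df.shape[1], int(df.values.sum()))
    return SiteCountMatrix(df)


def read_promoters(path) -> dict[str, str]:
    """Read promoter sequences from FASTA; record id = gene id."""
    promoters = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in promoters:
            raise InputError(f"duplicate promoter record {rec.id}")
        promoters[rec.id] = str(rec.seq).upper()
    if not promoters:
        raise InputError(f"no FASTA records in {path}")
    return promoters


def write_promoters(promoters: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for g, seq in promoters.items():
            fh.write(f">{g}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
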
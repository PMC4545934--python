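"""Position frequency/weight matrices and their information content.

A PFM is a 4xL matrix of (possibly real-valued) nucleotide counts from
aligned binding sites, rows in canonical A,C,G,T order. A PWM is the
log2-odds matrix derived from a PFM against an organism background model
with a pseudocount:

    w(i,k) = log2( v(i,k) / f_i ),   v(i,k) = (n(i,k) + f_i*mu) / (N_k + mu)

where N_k is the column count sum and f_i the background frequency of
nucleotide i. A window score is the sum of the weights of its bases; the
consensus score S_max is the sum of per-column maxima. Information content
is the summed per-column KL divergence (bits) between the adjusted column
distribution and the background.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError, ParseError

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: row permutation mapping A,C,G,T -> T,G,C,A
COMPLEMENT_ORDER = np.array([3, 2, 1, 0])

#: sentinel returned by :func:`score_window` for windows containing
#: non-ACGT symbols; distinguishable from any real score.
UNSCORABLE = float("nan")

# code table: byte -> 0..3, or -1 for anything not ACGT/acgt
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


@dataclass(frozen=True)
class BackgroundModel:
    """Genome-wide i.i.d. nucleotide frequencies (A, C, G, T)."""

    freq_a: float
    freq_c: float
    freq_g: float
    freq_t: float
    label: str = ""

    def __post_init__(self) -> None:
        f = self.freqs
        if np.any(f <= 0):
            raise ParameterError("background frequencies must all be > 0")
        if abs(float(f.sum()) - 1.0) > 1e-9:
            raise ParameterError(
                f"background frequencies must sum to 1, got {f.sum()!r}"
            )

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.freq_a, self.freq_c, self.freq_g, self.freq_t])

    @classmethod
    def from_gc(cls, gc_content: float, label: str = "") -> "BackgroundModel":
        at = (1.0 - gc_content) / 2.0
        gc = gc_content / 2.0
        return cls(at, gc, gc, at, label=label or f"gc={gc_content:g}")


#: organism presets: AT-rich genomes have f_A = f_T above 0.25
BACKGROUND_PRESETS = {
    "uniform": BackgroundModel(0.25, 0.25, 0.25, 0.25, label="uniform"),
    "fly": BackgroundModel(0.28, 0.22, 0.22, 0.28, label="fly"),
    "yeast": BackgroundModel(0.31, 0.19, 0.19, 0.31, label="yeast"),
    "vertebrate": BackgroundModel(0.29, 0.21, 0.21, 0.29, label="vertebrate"),
}


@dataclass
class PFM:
    """Raw nucleotide count matrix (rows A,C,G,T; columns motif positions).

    ``n_sequences`` is the number of validated binding sites behind the
    matrix; when a file carries no such metadata it defaults to the largest
    column sum rounded to the nearest integer (column sums of count PFMs
    equal the number of aligned sites, up to gaps).
    """

    counts: np.ndarray
    n_sequences: int
    motif_id: str = ""
    tf_name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ParameterError(
                f"PFM counts must be 4xL, got shape {self.counts.shape}"
            )
        if self.counts.shape[1] < 1:
            raise ParameterError("PFM must have at least one column")
        if np.any(self.counts < 0):
            raise ParameterError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ParameterError("every PFM column needs a positive count sum")
        if self.n_sequences <= 0:
            raise ParameterError("n_sequences must be positive")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWM:
    """Log2-odds weight matrix in bits, with its provenance and summaries."""

    weights: np.ndarray
    background: BackgroundModel
    pseudocount: float
    information_content: float
    source_pfm_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ParameterError("PWM weights must be 4xL")

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def s_max(self) -> float:
        """Consensus score: sum over columns of the per-column maximum."""
        return float(self.weights.max(axis=0).sum())

    @property
    def s_min(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))


def adjusted_frequencies(
    pfm: PFM, background: BackgroundModel, pseudocount: float = 1.0
) -> np.ndarray:
    """Pseudocount-adjusted per-column nucleotide probabilities.

    p(i,k) = (n(i,k) + f_i*mu) / (N_k + mu); columns sum to 1 exactly.
    """
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    f = background.freqs[:, None]
    col_sums = pfm.counts.sum(axis=0, keepdims=True)
    return (pfm.counts + f * pseudocount) / (col_sums + pseudocount)


def information_content(
    pfm: PFM, background: BackgroundModel, pseudocount: float = 1.0
) -> float:
    """Motif information content in bits.

    Sum over columns of KL(p_col || background) in log base 2; always >= 0,
    and 0 exactly when every adjusted column equals the background.
    """
    p = adjusted_frequencies(pfm, background, pseudocount)
    f = background.freqs[:, None]
    return float(np.sum(p * np.log2(p / f)))


def build_pwm(
    pfm: PFM, background: BackgroundModel, pseudocount: float = 1.0
) -> PWM:
    """Build the log2-odds PWM for ``pfm`` against ``background``."""
    p = adjusted_frequencies(pfm, background, pseudocount)
    weights = np.log2(p / background.freqs[:, None])
    return PWM(
        weights=weights,
        background=background,
        pseudocount=pseudocount,
        information_content=information_content(pfm, background, pseudocount),
        source_pfm_id=pfm.motif_id,
    )


def score_window(pwm: PWM, sequence: str, offset: int) -> float:
    """Score the L-mer of ``sequence`` starting at ``offset``.

    Returns :data:`UNSCORABLE` (NaN) if the window contains a non-ACGT
    symbol; raises if the window does not fit inside the sequence.
    """
    L = pwm.length
    if offset < 0 or offset + L > len(sequence):
        raise ParameterError(
            f"window [{offset}, {offset + L}) outside sequence of length "
            f"{len(sequence)}"
        )
    codes = encode_sequence(sequence[offset : offset + L])
    if np.any(codes < 0):
        return UNSCORABLE
    return float(pwm.weights[codes, np.arange(L)].sum())


def reverse_complement(pwm: PWM) -> PWM:
    """PWM scoring the reverse strand: columns reversed, A<->T and C<->G.

    S_max and information content are unchanged; an involution.
    """
    return replace(
        pwm,
        weights=pwm.weights[COMPLEMENT_ORDER][:, ::-1].copy(),
        source_pfm_id=pwm.source_pfm_id,
    )


def shift_weights(pwm: PWM, shifts) -> PWM:
    """Add a per-column constant to every weight (gauge shift).

    Shifts every window score and S_max by sum(shifts), leaving all score
    differences — and therefore lambda — unchanged.
    """
    shifts = np.broadcast_to(np.asarray(shifts, float), (pwm.length,))
    return replace(pwm, weights=pwm.weights + shifts[None, :])


def scale_weights(pwm: PWM, factor: float) -> PWM:
    """Multiply all weights by ``factor`` > 0.

    Scales every score difference by ``factor`` while the underlying motif
    (and its information content) is unchanged, so lambda scales by
    ``factor`` too.
    """
    if factor <= 0:
        raise ParameterError("scale factor must be > 0")
    return replace(pwm, weights=pwm.weights * factor)


def filter_pfms(
    pfms: list[PFM], min_sequences: int = 30, min_length: int = 6
) -> list[PFM]:
    """Drop PFMs built from too few sites or spanning too few base pairs.

    Keeps PFMs with n_sequences >= min_sequences and length >= min_length
    (both boundaries inclusive); order preserved; one log line per removal.
    """
    kept = []
    for pfm in pfms:
        if pfm.n_sequences < min_sequences:
            logger.info(
                "removed %s: %d reference sequences < %d",
                pfm.motif_id or "<unnamed>", pfm.n_sequences, min_sequences,
            )
        elif pfm.length < min_length:
            logger.info(
                "removed %s: length %d bp < %d bp",
                pfm.motif_id or "<unnamed>", pfm.length, min_length,
            )
        else:
            kept.append(pfm)
    return kept


# ---------------------------------------------------------------------------
# parsing

_ROW_RE = re.compile(
    r"^\s*(?:(?P<base>[ACGTacgt])\s*[:|]?\s*)?\[?\s*(?P<body>[-0-9.eE+\s]*?)\s*\]?\s*$"
)


def _parse_row(line: str, lineno: int, block: str):
    """Return (base_label_or_None, list_of_floats) for one matrix row."""
    m = _ROW_RE.match(line)
    if not m:
        raise ParseError(f"block '{block}', line {lineno}: unparsable row: {line!r}")
    base = m.group("base")
    body = m.group("body")
    try:
        values = [float(tok) for tok in body.split()]
    except ValueError as exc:
        raise ParseError(
            f"block '{block}', line {lineno}: non-numeric count: {exc}"
        ) from exc
    if not values:
        raise ParseError(f"block '{block}', line {lineno}: empty count row")
    if any(v < 0 for v in values):
        raise ParseError(f"block '{block}', line {lineno}: negative count")
    return (base.upper() if base else None, values)


def _finish_block(header, rows, start_line) -> PFM:
    motif_id, tf_name, meta = header
    block = motif_id or f"line {start_line}"
    if len(rows) != 4:
        raise ParseError(
            f"block '{block}', line {start_line}: expected 4 rows, got {len(rows)}"
        )
    lengths = {len(v) for _, v in rows}
    if len(lengths) != 1:
        raise ParseError(f"block '{block}', line {start_line}: ragged columns")
    labels = [b for b, _ in rows]
    matrix = np.zeros((4, len(rows[0][1])))
    if all(lab is not None for lab in labels):
        if sorted(labels) != list(BASES):
            raise ParseError(
                f"block '{block}', line {start_line}: row labels {labels} "
                "are not a permutation of A,C,G,T"
            )
        for lab, values in rows:
            matrix[BASE_INDEX[lab]] = values
    elif all(lab is None for lab in labels):
        for i, (_, values) in enumerate(rows):
            matrix[i] = values
    else:
        raise ParseError(
            f"block '{block}', line {start_line}: mix of labeled and "
            "unlabeled rows"
        )
    n_sequences = meta.get("n_sequences")
    if n_sequences is None:
        n_sequences = int(round(matrix.sum(axis=0).max()))
    return PFM(
        counts=matrix,
        n_sequences=max(n_sequences, 1),
        motif_id=motif_id,
        tf_name=tf_name,
    )


def parse_pfms(source, format_hint: str = "auto") -> list[PFM]:
    """Parse PFMs from JASPAR-style plain text.

    Accepts the ">ID NAME" headed dialect (rows ``A [ 8 0 ... ]`` or bare),
    headerless label-prefixed blocks, and bare 4-row whitespace matrices,
    freely mixed; blocks are separated by headers or blank lines. Row order
    is canonicalized to A,C,G,T whatever the file order. ``source`` may be a
    string, an open text handle, or a path-like pointing at a file.

    An optional ``; n_sequences=<int>`` token in a header line overrides
    the default site count (the rounded maximum column sum).
    """
    import os

    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)

    pfms: list[PFM] = []
    header = ("", "", {})
    rows: list = []
    start_line = 1
    in_block = False

    def flush():
        nonlocal rows, in_block
        if in_block:
            pfms.append(_finish_block(header, rows, start_line))
        rows, in_block = [], False

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith(">"):
            flush()
            head = stripped[1:].strip()
            meta = {}
            nmatch = re.search(r"n_sequences\s*=\s*(\d+)", head)
            if nmatch:
                meta["n_sequences"] = int(nmatch.group(1))
                head = head[: nmatch.start()].rstrip(" ;")
            parts = head.split(None, 1)
            header = (
                parts[0] if parts else "",
                parts[1] if len(parts) > 1 else "",
                meta,
            )
            start_line = lineno + 1
            continue
        if not stripped or stripped.startswith("#"):
            flush()
            header = ("", "", {})
            continue
        if not in_block:
            in_block = True
            start_line = lineno
            if header[0] == "":
                header = ("", "", {})
        block = header[0] or f"line {start_line}"
        rows.append(_parse_row(stripped, lineno, block))
        if len(rows) > 4:
            raise ParseError(
                f"block '{block}', line {lineno}: more than 4 rows "
                "(missing blank line between matrices?)"
            )
    flush()
    return pfms


def write_pwm_tsv(pwm: PWM, handle) -> None:
    """Serialize a PWM as TSV with ``#`` metadata header lines."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write(f"# pwm_id\t{pwm.source_pfm_id}\n")
        fh.write(f"# background\t{pwm.background.label}\n")
        fh.write(f"# pseudocount\t{pwm.pseudocount:g}\n")
        fh.write(f"# s_max_bits\t{pwm.s_max:.6f}\n")
        fh.write(f"# information_content_bits\t{pwm.information_content:.6f}\n")
        fh.write("base\t" + "\t".join(str(k) for k in range(pwm.length)) + "\n")
        for i, base in enumerate(BASES):
            fh.write(
                base + "\t" + "\t".join(f"{w:.6f}" for w in pwm.weights[i]) + "\n"
            )
    finally:
        if own:
            fh.close()
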
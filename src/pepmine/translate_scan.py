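"""Six-frame translation and exhaustive sliding-window peptide enumeration.

Every QC-passed read is translated in all six frames with the standard
genetic code, and every substring of 5-50 residues that is free of stop
codons ('*') and ambiguous codons ('X') becomes a candidate peptide window.
Step size is 1 (exhaustive enumeration); nucleotide coordinates are always
reported on the forward strand, 1-based inclusive, with the strand implied
by the frame sign.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = [
    "FrameTranslation",
    "PeptideWindow",
    "FRAMES",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "enumerate_windows",
    "window_count_closed_form",
]

FRAMES = (1, 2, 3, -1, -2, -3)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the standard code
_CODON_MAP = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a read: +1/+2/+3 forward, -1/-2/-3 reverse."""

    read_id: str
    frame: int
    peptide: str


@dataclass(frozen=True)
class PeptideWindow:
    """A stop-free candidate window with forward-strand coordinates."""

    window_id: str
    read_id: str
    frame: int
    pep_start: int  # 1-based inclusive on the frame translation
    pep_end: int
    sequence: str
    nt_start: int  # 1-based inclusive on the forward strand
    nt_end: int


def translate_frame(dna: str, frame: int) -> str:
    """Translate one frame; stops emit '*', N-containing codons emit 'X'."""
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}")
    seq = dna.upper() if frame > 0 else reverse_complement(dna.upper())
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append(_CODON_MAP.get(codon, "X"))
    return "".join(out)


def six_frame_translate(dna: str, read_id: str = "") -> list[FrameTranslation]:
    """All six frame translations of a read (trailing partial codons dropped)."""
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon cannot be translated")
    return [FrameTranslation(read_id, f, translate_frame(dna, f)) for f in FRAMES]


def _window_nt_coords(frame: int, pep_start: int, pep_end: int, read_length: int
                      ) -> tuple[int, int]:
    offset = abs(frame) - 1
    s = offset + 3 * (pep_start - 1) + 1
    e = offset + 3 * pep_end
    if frame > 0:
        return s, e
    return read_length - e + 1, read_length - s + 1


def enumerate_windows(translations: list[FrameTranslation], read_length: int,
                      wmin: int = 5, wmax: int = 50) -> list[PeptideWindow]:
    """All stop-free, X-free windows of length wmin..wmax, step 1."""
    if wmin < 1 or wmax < wmin:
        raise ValueError("require 1 <= wmin <= wmax")
    windows: list[PeptideWindow] = []
    for tr in translations:
        pep = tr.peptide
        # maximal clean segments between '*'/'X'
        seg_start = 0
        for seg in pep.replace("X", "*").split("*"):
            if len(seg) >= wmin:
                for w in range(wmin, min(wmax, len(seg)) + 1):
                    for i in range(len(seg) - w + 1):
                        ps = seg_start + i + 1
                        pe = ps + w - 1
                        nt_s, nt_e = _window_nt_coords(tr.frame, ps, pe, read_length)
                        wid = f"{tr.read_id}|{tr.frame:+d}|{nt_s}-{nt_e}"
                        windows.append(PeptideWindow(
                            wid, tr.read_id, tr.frame, ps, pe,
                            seg[i:i + w], nt_s, nt_e))
            seg_start += len(seg) + 1
    return windows


def window_count_closed_form(p: int, wmin: int = 5, wmax: int = 50) -> int:
    """Window count for a stop-free translation of length p."""
    return sum(p - w + 1 for w in range(wmin, min(wmax, p) + 1))
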
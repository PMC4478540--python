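"""Read quality preparation.

Raw paired reads are head-cropped (the first bases of each read are
systematically low quality on the instrument runs this models), adapter- and
quality-trimmed from the 3' end, length-filtered, and finally concatenated
into a single single-end stream — short BES reference fragments make paired
placement uninformative, so mates are treated as independent reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .simdata import _open_text


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PrepParams:
    head_crop: int = 13
    min_length: int = 40
    quality_threshold: int = 20
    adapter: str = ""
    # minimum exact overlap for a 3' adapter-prefix match to be trimmed
    min_adapter_overlap: int = 8

    def validate(self) -> None:
        if self.head_crop < 0:
            raise ValueError("head_crop must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def _trim_adapter(seq: str, params: PrepParams) -> int:
    """Return the cut index: the leftmost position whose suffix is an exact
    prefix of the adapter of length >= min_adapter_overlap."""
    adapter = params.adapter
    if not adapter:
        return len(seq)
    n = len(seq)
    for i in range(n - params.min_adapter_overlap + 1):
        tail = n - i
        if tail <= len(adapter) and seq[i:] == adapter[:tail]:
            return i
        if tail > len(adapter) and seq[i : i + len(adapter)] == adapter:
            return i
    return n


def _quality_cut(quals: Sequence[int], threshold: int) -> int:
    """3' running-sum trim: keep the prefix [0, i*) where i* maximises
    the suffix sum of (threshold - q); ties keep the longest read."""
    best_i, best_s, s = len(quals), 0, 0
    for i in range(len(quals) - 1, -1, -1):
        s += threshold - quals[i]
        if s > best_s:
            best_s, best_i = s, i
    return best_i


def prep_read(
    seq: str, quals: Sequence[int], params: PrepParams
) -> tuple[str, list[int]] | None:
    """Prepare one read; returns None when the survivor is too short."""
    if len(seq) != len(quals):
        raise FastqFormatError(
            f"sequence length {len(seq)} != quality length {len(quals)}"
        )
    seq = seq[params.head_crop :]
    quals = list(quals[params.head_crop :])
    cut = _trim_adapter(seq, params)
    seq, quals = seq[:cut], quals[:cut]
    cut = _quality_cut(quals, params.quality_threshold)
    seq, quals = seq[:cut], quals[:cut]
    if len(seq) < params.min_length:
        return None
    return seq, quals


def prep_fastq(
    fastq_paths: Iterable[str | Path],
    out_path: str | Path,
    params: PrepParams | None = None,
) -> dict[str, int]:
    """Prepare every read of the given FASTQ files (R1 then R2 order) and
    concatenate survivors into one single-end FASTQ. Returns tallies."""
    params = params or PrepParams()
    params.validate()
    n_in = n_out = 0
    with _open_text(out_path, "w") as out:
        for path in fastq_paths:
            with _open_text(path, "r") as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    n_in += 1
                    result = prep_read(
                        str(rec.seq), rec.letter_annotations["phred_quality"], params
                    )
                    if result is None:
                        continue
                    seq, quals = result
                    n_out += 1
                    qstr = "".join(chr(q + 33) for q in quals)
                    out.write(f"@{rec.id}\n{seq}\n+\n{qstr}\n")
    return {"input": n_in, "output": n_out, "discarded": n_in - n_out}
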
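"""FH1-domain poly-L-proline track (PBT) detection.

Formin FH1 domains recruit profilin-actin through poly-L-proline tracks.
A PBT is a run of more than three consecutive prolines; runs longer than 12
prolines are counted as multiple tracks.  The position of each track
relative to the FH2 domain matters mechanistically, so each track can be
annotated with its residue gap to the FH1/FH2 boundary.
"""

from __future__ import annotations

import re

from .datatypes import PBTrack, ProteinSequence

__all__ = ["find_pbts", "pbt_distance_to_fh2", "annotate_fh2_distances"]

#: Minimum qualifying run: more than three consecutive prolines.
MIN_RUN = 4
#: Runs longer than this are split into multiple tracks.
MAX_TRACK = 12


def find_pbts(seq: ProteinSequence) -> list[PBTrack]:
    """All poly-proline tracks in a sequence, ordered by start position.

    Maximal runs of >= 4 prolines qualify.  A run of L > 12 prolines is
    split greedily from the N-terminal side into chunks of 12 with the
    remainder last, yielding ceil(L/12) tracks; each resulting track records
    the length of the raw maximal run it came from (``run_length``) so that
    alternative splitting conventions can be recomputed.
    """
    tracks: list[PBTrack] = []
    for match in re.finditer(r"P{%d,}" % MIN_RUN, seq.residues):
        start, end = match.start() + 1, match.end()  # 1-based inclusive
        run_length = end - start + 1
        if run_length <= MAX_TRACK:
            tracks.append(PBTrack(start=start, end=end, run_length=run_length))
        else:
            pos = start
            while pos <= end:
                chunk_end = min(pos + MAX_TRACK - 1, end)
                tracks.append(PBTrack(start=pos, end=chunk_end, run_length=run_length))
                pos = chunk_end + 1
    return tracks


def pbt_distance_to_fh2(track: PBTrack, fh2_start: int) -> int:
    """Residues strictly between the track end and the FH2 domain start."""
    if fh2_start <= track.end:
        raise ValueError("track must lie upstream of the FH2 start")
    return fh2_start - track.end - 1


def annotate_fh2_distances(tracks: list[PBTrack], fh2_start: int) -> list[PBTrack]:
    """Return tracks annotated with their gap to the FH1/FH2 boundary."""
    return [
        PBTrack(
            start=t.start,
            end=t.end,
            run_length=t.run_length,
            distance_to_fh2=pbt_distance_to_fh2(t, fh2_start),
        )
        for t in tracks
    ]
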
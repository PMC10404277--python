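import numpy as np
import pytest

from polyte.models import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_uorf_transcript():
    """Transcript with one contained uORF and one overlapping out-of-frame uORF.

    Layout (0-based):
      0-1    AA
      2-10   uORF1: AUG GCU UAA          (contained in the 5'UTR)
      11-13  CCC
      14-16  uORF2 AUG, 4 nt upstream of the main AUG -> frame 2
      17     C
      18-29  main CDS: AUG AAA CUA ... actually AUG AAA GGG UAA
      30-35  3'UTR
    """
    utr5 = "AA" + "AUGGCUUAA" + "CCC" + "AUG" + "C"
    cds = "AUGAAAGGGUAA"
    seq = utr5 + cds + "CCAACC"
    return TranscriptModel("tx1", seq, len(utr5), len(utr5) + len(cds), "gene1")


def brute_force_uorf_scan(t: TranscriptModel):
    """Independent oracle: naive AUG scan + triplet walk over the 5'UTR.

    Deliberately written without reference to polyte.uorf internals.
    """
    stops = {"UAA", "UAG", "UGA"}
    found = []
    for i in range(t.cds_start):
        if t.sequence[i : i + 3] != "AUG":
            continue
        stop_end = None
        n = 0
        j = i
        while j + 3 <= len(t.sequence):
            n += 1
            if t.sequence[j : j + 3] in stops:
                stop_end = j + 3
                break
            j += 3
        frame = (i - t.cds_start) % 3
        if stop_end is not None and stop_end <= t.cds_start:
            klass = "contained_in_utr"
        elif frame != 0:
            klass = "overlapping_out_of_frame"
        else:
            klass = "overlapping_in_frame"
        found.append((i, stop_end, n, frame, klass))
    return found


def random_transcript(rng, min_utr=5, max_utr=60, min_codons=5, max_codons=40):
    """Random transcript with unconstrained 5'UTR content (AUGs allowed)."""
    bases = np.array(list("ACGU"))
    utr5_len = int(rng.integers(min_utr, max_utr + 1))
    n_codons = int(rng.integers(min_codons, max_codons + 1))
    utr5 = "".join(rng.choice(bases, size=utr5_len))
    body = "".join(rng.choice(bases, size=3 * (n_codons - 2)))
    cds = "AUG" + body + "UAA"
    utr3 = "".join(rng.choice(bases, size=int(rng.integers(0, 40))))
    return TranscriptModel("rt", utr5 + cds + utr3, utr5_len, utr5_len + len(cds))
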
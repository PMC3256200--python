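import numpy as np
import pytest

from chromocorr.genome_io import FeatureSet, GenomeInterval, MaskSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_pair_counts(x, edges, y=None):
    """O(N^2) / O(N*M) double-loop oracle for binned pair tallies.

    Auto mode (y is None): unordered pairs i < j. Cross mode: all ordered
    pairs. Separations outside [edges[0], edges[-1]) are discarded.
    """
    x = np.asarray(x)
    edges = np.asarray(edges, dtype=float)
    k = edges.size - 1
    out = np.zeros(k, dtype=np.int64)
    if y is None:
        seps = [abs(int(x[i]) - int(x[j]))
                for i in range(len(x)) for j in range(i + 1, len(x))]
    else:
        y = np.asarray(y)
        seps = [abs(int(a) - int(b)) for a in x for b in y]
    for s in seps:
        for b in range(k):
            if edges[b] <= s < edges[b + 1]:
                out[b] += 1
                break
    return out


def make_features(starts, chrom_length, length=1, chrom="chr"):
    ivs = tuple(GenomeInterval(chrom, int(s), int(s) + length) for s in sorted(starts))
    return FeatureSet(chrom, ivs, chrom_length)


def make_mask(spans, chrom_length, chrom="chr"):
    ivs = tuple(GenomeInterval(chrom, int(s), int(e)) for s, e in spans)
    return MaskSet(chrom, ivs, chrom_length)
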
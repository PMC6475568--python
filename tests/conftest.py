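import itertools

import pysam
import pytest

from delscreen import synthetic

_counter = itertools.count()


@pytest.fixture
def bam_factory(tmp_path):
    """Build tiny coordinate-sorted, indexed BAMs from explicit pair coordinates.

    ``pairs`` is a list of (m1_start, m1_end, m2_start, m2_end, mapq1, mapq2)
    tuples; ``singles`` a list of (start, end, mapq, flag) for unpaired or
    otherwise special reads.
    """

    def make(pairs, chrom="chrT", chrom_length=1_000_000, singles=()):
        path = tmp_path / f"mini{next(_counter)}.bam"
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": chrom_length}],
        }
        records = []
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for i, (s1, e1, s2, e2, q1, q2) in enumerate(pairs):
                for (s, e, q, flag, ms) in (
                    (s1, e1, q1, 99, s2),
                    (s2, e2, q2, 147, s1),
                ):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"pair{i}"
                    a.flag = flag
                    a.reference_id = 0
                    a.reference_start = s
                    a.mapping_quality = q
                    a.cigarstring = f"{e - s}M"
                    a.next_reference_id = 0
                    a.next_reference_start = ms
                    a.template_length = max(e1, e2) - min(s1, s2)
                    records.append(a)
            for j, (s, e, q, flag) in enumerate(singles):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"single{j}"
                a.flag = flag
                a.reference_id = 0
                a.reference_start = s
                a.mapping_quality = q
                a.cigarstring = f"{e - s}M"
                a.next_reference_id = -1
                a.next_reference_start = -1
                records.append(a)
            for a in sorted(records, key=lambda r: r.reference_start):
                out.write(a)
        pysam.index(str(path))
        return str(path)

    return make


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A shared small synthetic dataset (full outputs on disk)."""
    cfg = synthetic.SimConfig(
        seed=7,
        chrom_length=600_000,
        n_true_deletions=3,
        n_bias_artifacts=3,
        bias_true_deletions=True,
        n_decoys=5,
    )
    out_dir = tmp_path_factory.mktemp("smallsim")
    outputs = synthetic.simulate(cfg, str(out_dir))
    return cfg, outputs
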
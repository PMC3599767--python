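import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tilemeta import ProbeMatrix, SampleTable, ScoredDER

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_matrix_file(tmp_path):
    """A well-formed 3-probe x 4-sample matrix file."""
    path = tmp_path / "matrix.tsv"
    path.write_text(
        "probe_id\tchrom\tposition\ts1\ts2\ts3\ts4\n"
        "p1\tchr1\t100\t0.1\t0.2\t0.3\t0.4\n"
        "p2\tchr1\t135\t0.5\t0.6\t0.7\t0.8\n"
        "p3\tchr1\t170\t-0.1\tNA\t0.1\t0.2\n"
    )
    return path


@pytest.fixture
def annot_file(tmp_path):
    path = tmp_path / "annot.tsv"
    path.write_text(
        "sample_id\tgroup\n"
        "s1\tcontrol\n"
        "s2\tcontrol\n"
        "s3\tcase\n"
        "s4\tcase\n"
    )
    return path


def make_matrix(values, positions=None, chrom=None, sample_ids=None):
    """Build a ProbeMatrix from a raw value array with default coordinates."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if positions is None:
        positions = 100 + 35 * np.arange(n_probes)
    if chrom is None:
        chrom = ["chr1"] * n_probes
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    probe_ids = [f"p{i + 1}" for i in range(n_probes)]
    return ProbeMatrix(np.array(probe_ids, dtype=object), np.array(chrom, dtype=object),
                       np.asarray(positions), values, sample_ids)


def make_annot(groups, sample_ids=None, **extra_cols):
    groups = list(groups)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(groups))]
    data = {"group": groups, **extra_cols}
    return SampleTable(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))


def make_der(chrom="chr1", start=100, end=205, n_probes=3, direction=1,
             mean_diff=0.3, max_diff=0.4, Q=5.0, p=0.01, q_fdr=0.02,
             first_probe=-1, last_probe=-1):
    return ScoredDER(chrom, start, end, n_probes, direction, mean_diff,
                     max_diff, Q, p, q_fdr, first_probe, last_probe)
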
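import sys
from pathlib import Path

import numpy as np
import pytest

# Make the sibling oracles module importable regardless of invocation dir.
sys.path.insert(0, str(Path(__file__).parent))

from gcmosaic import FamilySpec, GenomeSpec


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write a FASTA file from (id, sequence) pairs; returns the path."""

    def _write(entries, name="test.fasta", line_width=60):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in entries:
                fh.write(f">{rec_id}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
        return path

    return _write


@pytest.fixture
def two_family_spec():
    """A 50/50 mosaic of 35%- and 48%-GC families on a small multi-chromosome genome."""
    return GenomeSpec(
        families=(FamilySpec(35.0, 0.5), FamilySpec(48.0, 0.5)),
        n_chromosomes=4,
        chromosome_length=1_000_000,
        window_noise_sd=1.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
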
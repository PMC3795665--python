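import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rdnarray import RepeatReference
from rdnarray.pileup import Pileup


@pytest.fixture
def small_ref() -> RepeatReference:
    # 20 bp unit with two annotated regions
    return RepeatReference(
        "unit",
        "ACGTACGTGGCCAATTACGT",
        regions=(),
    )


@pytest.fixture
def annotated_ref() -> RepeatReference:
    from rdnarray import Region

    return RepeatReference(
        "unit",
        "ACGTACGTGGCCAATTACGT",
        regions=(Region("18S", 3, 8), Region("ITS", 9, 14)),
    )


def make_pileup(counts_by_position: dict[int, dict[str, int]], length: int, ref_id="unit") -> Pileup:
    """Build a pileup from {1-based position: {allele: count}}."""
    from rdnarray.pileup import ALLELES

    pl = Pileup(ref_id, length)
    for pos, tab in counts_by_position.items():
        for allele, n in tab.items():
            pl.counts[pos - 1, ALLELES.index(allele)] += n
    return pl


@pytest.fixture
def pileup_factory():
    return make_pileup


def write_fasta(path: Path, records: list[tuple[str, str]]) -> Path:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def fasta_writer():
    return write_fasta
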
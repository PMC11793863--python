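import warnings

import numpy as np
import pytest

from nirstreat.montage import Montage, TaskParadigm, load_montage


@pytest.fixture(scope="session")
def montage() -> Montage:
    return load_montage()


@pytest.fixture(scope="session")
def paradigm() -> TaskParadigm:
    return TaskParadigm()


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the replication-mode leakage warning that many tests trigger."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="projection fitted on all NR subjects"
        )
        warnings.filterwarnings("ignore", message=".*subjects missing a modality.*")
        yield


def brute_force_neighbors(montage: Montage, channel: str) -> set[str]:
    """Independent optode-sharing enumeration used as the neighbour oracle."""
    own = set(montage.optode_pairs[channel])
    out = set()
    for other in montage.in_use_mask:
        if other == channel:
            continue
        if own & set(montage.optode_pairs[other]):
            out.add(other)
    return out
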
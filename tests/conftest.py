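from io import StringIO

import pytest
from skbio import TreeNode

from gutwash.model import DoseEvent, FeedingSchedule, ReactorChain


@pytest.fixture
def single_chain():
    return ReactorChain.from_volumes([("AC", 500.0)])


@pytest.fixture
def three_chain():
    return ReactorChain.from_volumes([("AC", 500.0), ("TC", 800.0), ("DC", 600.0)])


@pytest.fixture
def schedule():
    return FeedingSchedule(transfer_volume=140.0, cycles_per_day=3)


@pytest.fixture
def dose():
    # 5e6 cells/mL into the 500 mL first vessel
    return DoseEvent("AC", 0, 2.5e9)


@pytest.fixture
def worked_tree():
    """Four-tip tree with total branch length 6, used for hand-checked PD values."""
    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
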
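import time
from collections import namedtuple

import pytest

from dnassign import EXAMPLE_2X3, EXAMPLE_3X5, solve
from dnassign.design import load_demo_code

TimedSolve = namedtuple("TimedSolve", ["result", "seconds"])


@pytest.fixture(scope="session")
def solved_2x3():
    return solve(EXAMPLE_2X3)


@pytest.fixture(scope="session")
def solved_3x5():
    start = time.perf_counter()
    result = solve(EXAMPLE_3X5)
    return TimedSolve(result, time.perf_counter() - start)


@pytest.fixture(scope="session")
def demo_code():
    return load_demo_code()
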
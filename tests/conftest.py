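import numpy as np
import pytest

from greycast import load_fixture

# Published GM(1,1) fitted values for the packaged accident-death series,
# 2000-2020, used to pin the classical fit (3-decimal print precision).
PRINTED_GM = np.array(
    [
        120350.239, 153846.738, 142948.842, 132822.911, 123414.260,
        114672.081, 106549.164, 99001.642, 91988.756, 85472.636,
        79418.092, 73792.428, 68565.264, 63708.371, 59195.522,
        55002.345, 51106.196, 47486.035, 44122.311, 40996.861,
        38092.805,
    ]
)


@pytest.fixture(scope="session")
def accident_series():
    return load_fixture("accident_deaths_2000_2020").series


@pytest.fixture(scope="session")
def printed_gm_column():
    return PRINTED_GM
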
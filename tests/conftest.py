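import numpy as np
import pytest

WATER_ITP = """\
; minimal rigid 3-site water topology
[ moleculetype ]
; name  nrexcl
SOL     2

[ atoms ]
;   nr  type   resnr residu  atom  cgnr    charge     mass
     1  OT     1     SOL     OW    1      -0.834   15.9994
     2  HT     1     SOL     HW1   1       0.417     1.008
     3  HT     1     SOL     HW2   1       0.417     1.008

[ settles ]
; OW funct doh dhh
1 1 0.09572 0.15139
"""


@pytest.fixture
def water_itp() -> str:
    return WATER_ITP


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
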
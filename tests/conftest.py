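import numpy as np
import pytest

from reburnscape.fire_history import BurnHistory, SeverityStack


@pytest.fixture
def tiny_stack():
    """3-year, 4x5 severity stack with hand-placed burns.

    Severity 3 = burned, 1 = unburned, nodata = -9999 in one corner.
    Cell size 10; extent x in [0, 50], y in [0, 40].
    """
    years = (2000, 2001, 2002)
    grids = np.ones((3, 4, 5), dtype=np.int16)
    grids[0, 0, 0] = 3          # top-left cell burns in 2000
    grids[0, 3, 4] = 3          # bottom-right cell burns in 2000
    grids[2, 3, 4] = 3          # ... and again in 2002
    grids[1, 1, 1] = -9999      # nodata cell in 2001
    return SeverityStack(years=years, grids=grids, cell_size=10.0, nodata=-9999)


@pytest.fixture
def table1_histories():
    """10 points with burn counts [0,0,0,1,1,1,1,2,2,3] over 1984-2016."""
    counts = [0, 0, 0, 1, 1, 1, 1, 2, 2, 3]
    histories = []
    for i, c in enumerate(counts):
        years = tuple(1990 + 5 * k for k in range(c))
        histories.append(BurnHistory(point_id=i, burn_years=years))
    return histories
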
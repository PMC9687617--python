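"""Generate one realistic breast phantom per density class.

Each phantom is an elliptical cross-section with a skin annulus and an
interior segmented into adipose / transitional / fibroglandular tissue;
per-pixel dielectric values are drawn from tissue-specific distributions.
"""

import numpy as np

from mwtbreast import GeneratorConfig, ImagingGrid, generate_phantom, \
    measure_skin_thickness
from mwtbreast.phantoms import ADIPOSE, FIBROGLANDULAR, TRANSITIONAL

grid = ImagingGrid()          # 15 cm x 15 cm, 108 x 108 pixels
cfg = GeneratorConfig()

print("class  fib%  trans%  adip%   skin[mm]  mean eps'  mean sigma")
for cls in "ABCD":
    p = generate_phantom(cfg, cls, grid, seed=2024)
    interior = np.isin(p.tissue_map, [ADIPOSE, TRANSITIONAL,
                                      FIBROGLANDULAR])
    n = interior.sum()
    fib = 100 * (p.tissue_map == FIBROGLANDULAR).sum() / n
    tra = 100 * (p.tissue_map == TRANSITIONAL).sum() / n
    adi = 100 * (p.tissue_map == ADIPOSE).sum() / n
    skin_mm = 1e3 * measure_skin_thickness(p, grid)
    print(f"  {cls}   {fib:5.1f}  {tra:5.1f}  {adi:5.1f}    "
          f"{skin_mm:5.2f}    {p.eps_map[interior].mean():6.1f}    "
          f"{p.sigma_map[interior].mean():6.3f}")

# The fibroglandular share rises from class A (mostly fatty) to class D
# (extremely dense); denser classes carry higher mean permittivity and
# conductivity because fibroglandular tissue has high water content.
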
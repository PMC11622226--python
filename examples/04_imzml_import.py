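"""Convert a centroided imzML file into the flat datacube format.

Writes a toy 2x2-pixel imzML/ibd pair, bins each spectrum's centroids
onto a three-peak list (+-0.01 Da windows), and prints the resulting
cube. Real peak-picked imzML exports convert the same way.
"""

import tempfile
from pathlib import Path

import numpy as np
from pyimzml.ImzMLWriter import ImzMLWriter

import msipca

workdir = Path(tempfile.mkdtemp(prefix="msipca_example_"))
imzml = workdir / "toy.imzML"
with ImzMLWriter(str(imzml)) as w:
    w.addSpectrum(np.array([100.000, 100.005, 200.0]), np.array([5.0, 3.0, 7.0]), coords=(1, 1, 1))
    w.addSpectrum(np.array([99.995, 150.0]), np.array([4.0, 6.0]), coords=(2, 1, 1))
    w.addSpectrum(np.array([150.002, 200.008]), np.array([2.0, 1.0]), coords=(1, 2, 1))
    w.addSpectrum(np.array([100.02]), np.array([9.0]), coords=(2, 2, 1))

peaks = msipca.PeakList((100.0, 150.0, 200.0), tolerance=0.01, tolerance_unit="da")
cube = msipca.convert_imzml(imzml, peaks, workdir / "cube")
print(f"converted {imzml.name}: {cube.meta.n_spectra} spectra x {cube.meta.n_peaks} peaks, "
      f"region grid {cube.meta.regions[0].width}x{cube.meta.regions[0].height}")
print("intensity matrix (rows = pixels, cols = peaks at 100/150/200 Da):")
print(cube.read_all())
print("  -> pixel 1 sums 5+3 at 100 Da; the 100.02 Da centroid of pixel 4 falls outside its window")
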
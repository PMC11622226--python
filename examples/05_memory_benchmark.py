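"""RAM footprint of the incremental fit: bounded by batch size, not cube size.

Fits two cubes of very different lengths under a 15 ms resident-memory
trace and reports peak-minus-resting RAM: the attributable footprint
stays flat as the cube grows, and grows with the batch size instead.
"""

import tempfile
from pathlib import Path

import msipca
from msipca.bench import StageTimer, trace_callable

workdir = Path(tempfile.mkdtemp(prefix="msipca_example_"))

for n_spectra in (20_000, 80_000):
    spec = msipca.SyntheticSpec(n_spectra=n_spectra, n_peaks=40, rank=4, seed=5)
    cube, _ = msipca.generate_datacube(spec, workdir / f"cube_{n_spectra}")
    timer = StageTimer()

    def work():
        with timer.stage("fit"):
            return msipca.fit(cube, batch_size=760)

    _, trace = trace_callable(work, interval=0.015)
    print(f"{n_spectra:>7} spectra ({cube.meta.size_mb:>3} MB cube): "
          f"fit {timer.durations['fit']:.2f} s, "
          f"peak - resting RAM = {trace.peak_minus_resting / 1e6:.1f} MB "
          f"({len(trace.samples)} samples)")
print("  -> quadrupling the cube barely moves the fit's RAM footprint")
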
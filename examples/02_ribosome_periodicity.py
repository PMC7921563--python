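"""Detect the 3-nt periodicity of ribosome footprints on coding transcripts.

Simulates footprints whose 5' ends are 80% in-frame (codon-start phased),
builds the pairwise 5'-end distance spectrum, and takes its discrete-
Fourier periodogram.  Translating ribosomes step one codon at a time, so
the dominant period should be 3 nt; a library with uniform 5' ends shows
no such peak.
"""

from intactrna import SimConfig, simulate
from intactrna.ribosome import distance_spectrum, periodogram, select_rpfs

for frac in (0.8, 0.0):
    cfg = SimConfig(seed=11, rpf_in_frame_fraction=frac)
    truth = simulate.simulate_reference(cfg)
    rpfs, _ = simulate.simulate_rpfs(truth, cfg)
    selected = select_rpfs(rpfs)  # 26-32 nt footprints
    spectrum = distance_spectrum(selected, max_distance=100)
    result = periodogram(spectrum)
    peak_rel = max(result.relative_density)
    print(f"in-frame fraction {frac:.0%}: {len(selected)} footprints, "
          f"dominant period = {result.dominant_period:.2f} nt, "
          f"peak relative density = {peak_rel:.1f}")
# the phased library peaks at ~3 nt (frequency 1/3); the uniform one has a
# flat periodogram whose argmax is an arbitrary low-power frequency
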
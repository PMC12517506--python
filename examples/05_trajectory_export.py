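"""Export a short trajectory for molecular viewers (PSF + XYZ).

Runs a miniature scenario with frames every 0.5 s and writes a
fixed-capacity PSF topology plus multi-frame XYZ coordinates (um); inactive
particle slots are parked at a sentinel position outside the domain so the
atom count stays constant.
"""

from pathlib import Path

from lamelliflow import Scenario, build_reference_config, run
from lamelliflow.io import bundle_from_frames, write_trajectory

params = build_reference_config(domain_size=(1.25, 0.625, 0.1), dt=4.6e-5,
                                assembly_time_cap=2.0)
scenario = Scenario(duration=2.0, seed=4, base=params, frame_every=0.5)
result = run(scenario)

bundle = bundle_from_frames(result.state, result.frames)
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
psf, xyz = write_trajectory(bundle, out / "mini_trajectory")
print("frames written :", len(bundle.frames))
print("atoms per frame:", bundle.n_atoms, "(constant across frames)")
print("topology       :", psf)
print("coordinates    :", xyz)
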
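"""Instrument and GPU parameter presets.

The five instrument presets span the main CT application areas: an
industrial micro CT (bench measurements on a commercial scanner), an
in-lab nano CT, a clinical 16-slice medical CT, a large-scale MV cargo
scanner, and an electron-beam CT (EBCT) densitometer whose deflected
beam makes angle changeover nearly free.  Times are seconds, angles
degrees.  Zero entries are parameters unavailable from vendor data and
presumed negligible.

Note on the nano preset: its commonly quoted full-scan total (~4.9e4 s)
is not consistent with the per-projection parameters below, which imply
~1.45e5 s (800 x (180 + 1) s of exposure alone).  The preset is provided
for completeness; treat its modeled total as parameter-faithful rather
than matching that quoted figure.
"""

from __future__ import annotations

SETUP_PRESETS: dict[str, dict] = {
    "micro": dict(
        name="micro",
        n_proj=512,
        angle_range=360.0,
        t_frame=1.0,
        time_per_rotation=60.0,
        c_det=1.0,
        c_move=0.1,
        gate=1,
        c_gate_move=0.0,
        c_gate_dose=0.1,
        continuous=False,
        n_x=2048,
        n_z=2048,
    ),
    "nano": dict(
        name="nano",
        n_proj=800,
        angle_range=180.0,
        t_frame=180.0,
        time_per_rotation=60.0,
        c_det=1.0,
        c_move=0.1,
        gate=0,
        c_gate_move=0.0,
        c_gate_dose=0.0,
        continuous=False,
        n_x=2048,
        n_z=2048,
    ),
    "medical": dict(
        name="medical",
        n_proj=720,
        angle_range=360.0,
        t_frame=0.00138,
        time_per_rotation=1.0,
        c_det=0.0,
        c_move=0.0,
        gate=0,
        c_gate_move=0.0,
        c_gate_dose=0.0,
        continuous=True,
        n_x=736,
        n_z=16,
    ),
    "cargo": dict(
        name="cargo",
        n_proj=720,
        angle_range=256.0,
        t_frame=0.0833,
        time_per_rotation=60.0,
        c_det=0.0,
        c_move=0.0,
        gate=0,
        c_gate_move=0.0,
        c_gate_dose=0.0,
        continuous=True,
        n_x=1360,
        n_z=1,
    ),
    # EBCT: the electron beam is steered, not a gantry; angle changeover
    # cost is a small constant independent of angular distance, modeled
    # as c_move with a zero rotation-time term.
    "ebct": dict(
        name="ebct",
        n_proj=400,
        angle_range=360.0,
        t_frame=7e-5,
        time_per_rotation=0.0,
        c_det=0.0,
        c_move=1e-5,
        gate=1,
        c_gate_move=0.0,
        c_gate_dose=0.0,
        continuous=False,
        n_x=720,
        n_z=2,
    ),
}

GPU_PRESETS: dict[str, dict] = {
    # Current-generation consumer GPU used for the reconstruction-cost
    # model: peak compute, PCIe host->device bandwidth, device memory
    # bandwidth, and empirical per-voxel / per-pixel operation counts
    # calibrated on commercial reconstruction software.
    "rtx4090": dict(
        name="rtx4090",
        s_rec=85.2e12,      # flop/s
        s_load=500e6,       # B/s over PCIe
        s_memory=1e12,      # B/s device memory
        p_voxel=600.0,      # ops per voxel per projection
        p_pixel=200.0,      # ops per projection pixel (preprocessing)
        ram_bytes=24e9,
    ),
    # Previous-generation card of the validation workstation.
    "rtx3080ti": dict(
        name="rtx3080ti",
        s_rec=34.1e12,
        s_load=500e6,
        s_memory=0.9e12,
        p_voxel=600.0,
        p_pixel=200.0,
        ram_bytes=12e9,
    ),
}
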
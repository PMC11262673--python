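"""How many reconstructions fit inside one acquisition?

Evaluates the GPU reconstruction-cost model for batch FBP/FDK, 50-iteration
SIRT, and the single-projection incremental partial update, on each
instrument's detector geometry, then divides the modeled acquisition time
by the cycle time.  Counts below one mean real-time reconstruction is
impossible on that instrument; the incremental update buys three to five
orders of magnitude over re-running batch reconstructions.
"""

import mtrsim as m

gpu = m.load_gpu_preset("rtx4090")
setups = [m.load_setup_preset(s) for s in ("micro", "nano", "medical", "cargo")]
table = m.cost_table(gpu, setups, sirt_iterations=50)

pretty = table.assign(
    cycle_time_s=table.cycle_time_s.map("{:.3g}".format),
    t_acq_s=table.t_acq_s.map("{:.3g}".format),
    per_n_p=table.per_n_p.map("{:.3g}".format),
)
print(pretty.to_string(index=False))

calib = m.recon_time(gpu, m.ReconJob(1000, 1000, 500, "fbp_fdk"))
print(
    f"\ncalibration case (1000x1000 detector, 500 projections): "
    f"{calib.t_total:.2f} s total "
    f"(kernel {calib.t_rec:.2f} s, preprocessing {calib.t_prep * 1e3:.2f} ms)"
)
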
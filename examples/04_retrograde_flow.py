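"""A desk-scale retrograde-flow run.

Self-assembles the branched network in a reduced (2.5 x 1.25 x 0.1 um)
domain, switches on motor walking, and prints the flow speed, density
heterogeneity (CV) and total substrate force over the steady phase.  Flow
is the mean retrograde (-y) velocity of actin near the leading edge in
nm/s; CV below ~1 indicates a reasonably homogeneous network.

Takes a few minutes on one core.
"""

from lamelliflow import reduced_scenario, run

scenario = reduced_scenario(seed=1, duration=10.0)
result = run(scenario)
rec = result.record

print("t (s)   flow (nm/s)   CV      substrate force (pN)   links")
for i, t in enumerate(rec.density_times):
    flow = ""
    if t in rec.flow_times:
        flow = "%8.1f" % rec.flow_nm_s[rec.flow_times.index(t)]
    print("%5.0f   %9s   %5.2f   %8.1f               %4d" % (
        t, flow, rec.cv[i], rec.force_pN[i], rec.n_links[i]))
print()
print("mean flow (t >= 4 s): %.2f nm/s" % rec.mean_flow(4.0))
print("bound motor arms at the end: %d" %
      int((result.state.mot_bound >= 0).sum()))
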
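"""Tidal modulation of near-bed particle flow, end to end.

Runs the full recovery experiment: render a 3-day deployment at 20-min
segment cadence, estimate each segment's dominant flow with DPIV, and
correlate it with the smoothed sea-level rate. Takes a few seconds.
"""

from fjordcam.pipeline import simulate_and_recover_flow

res = simulate_and_recover_flow(seed=0, days=3.0)
cs, cv = res["corr_signed"], res["corr_speed"]
print(f"r(sea-level rate, signed flow along axis) = {cs.r:+.3f} "
      f"(p = {cs.p_value:.2g}, n = {cs.n})")
print(f"r(|sea-level rate|, flow speed)           = {cv.r:+.3f} "
      f"(p = {cv.p_value:.2g}, n = {cv.n})")
print(f"mean direction rising tide:  {res['direction_rising_deg']:6.1f} deg")
print(f"mean direction falling tide: {res['direction_falling_deg']:6.1f} deg "
      f"(separation {res['direction_separation_deg']:.1f} deg)")
print("A positive first correlation and a ~180 deg separation mean the "
      "recovered flow reverses at slack water and speeds up with the tide, "
      "as imposed by the generator.")
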
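"""Find the puncture event in a noisy force-displacement trace.

Simulates one compression trial — a Hertz-like loading ramp with a sharp
40% force drop at the moment of puncture, plus 0.2 N sensor noise — and
runs the drop detector on it.  Real Instron-style CSV exports load the
same way via `puncture.read_force_trace`.
"""

from spinemech import puncture, synth

params = synth.TraceGenParams(
    puncture_force=10.31,       # embedded puncture force, N
    puncture_displacement=2.0,  # mm of indentation at puncture
    drop_fraction=0.4,          # fraction of the peak lost at puncture
    noise_sd=0.2,               # N
    travel_limit=5.0,           # mm
    seed=7,
)
trace, truth = synth.simulate_force_trace(params)
events = puncture.detect_puncture(trace)

print(f"samples in trace : {len(trace)}")
print(f"embedded event   : {truth[0].force:.2f} N at {truth[0].displacement:.2f} mm")
for ev in events:
    print(
        f"detected event   : peak {ev.peak_force:.2f} N at "
        f"{ev.peak_displacement:.2f} mm, drop {ev.drop_magnitude:.2f} N "
        f"({100 * ev.drop_fraction:.0f}%) over {ev.drop_width:.2f} mm"
    )
record = puncture.score_trial(trace)
print(f"trial outcome    : success={record.success}, force={record.puncture_force:.2f} N")
print()
print("A sharp, persistent force drop is the signature of the tool breaking")
print("through the substrate surface; the peak force right before the drop is")
print("the puncture force for the trial.")
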
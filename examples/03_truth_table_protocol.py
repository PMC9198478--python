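"""Drive the neuron through the four feature-binding episodes.

Each table row becomes an independent episode: the active inputs fire one
simultaneous spike, and the episode's Boolean output is 1 iff the soma
spikes.  Calibration first scales the synaptic drive and places the
threshold between the subthreshold peaks of the two output classes.  The
saturating neuron reproduces the table; its LIF counterpart responds
identically to every pattern and is reported not calibratable.
"""

from sifneuron import ProtocolConfig, default_sif_spec, implements_table, make_cfbp, make_lif

config = ProtocolConfig(table=make_cfbp(2), mode="spike")
sif = default_sif_spec()

for name, spec in [("SIF", sif), ("LIF", make_lif(sif))]:
    report = implements_table(spec, config)
    print(f"--- {name} ---")
    cal = report.calibration
    if cal.calibratable:
        print(
            f"calibrated: drive x{cal.drive_scale:g}, threshold {cal.v_threshold_mv:.3f} mV "
            f"(margin {cal.margin_mv:.3f} mV)"
        )
        for r, expected in zip(report.readouts, report.expected):
            print(
                f"  pattern {''.join(map(str, r.pattern))}: {r.somatic_spike_count} somatic "
                f"spike(s) -> output {r.output} (table says {expected})"
            )
    else:
        print(f"not calibratable: {cal.reason}")
    print(f"implements the table: {report.implements}\n")
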
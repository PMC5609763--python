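# Illustrative 31P cardiac prior knowledge (7 T peak set: PCr, the three
# ATP multiplets, PDE and the two 2,3-DPG resonances).  Chemical shifts are
# literature ballpark values referenced to PCr at 0 ppm; bounds and starting
# values are repository fixtures for testing and examples, not calibrated
# clinical settings.  All peaks share one zero-order phase (broadband
# excitation after first-order phase correction).
version: 1
peaks:
  - name: PCR
    shift_start: 0.0
    shift_lower: -0.2
    shift_upper: 0.2
    linewidth_start: 8.0
    linewidth_lower: 2.0
    linewidth_upper: 40.0
    amplitude_start: 1.0
    group_phase: global
  - name: ATP_GAMMA
    shift_start: -2.48
    linewidth_start: 12.0
    linewidth_lower: 2.0
    linewidth_upper: 60.0
    multiplet:
      n_components: 2
      j_hz: 16.0
      amplitude_ratios: [1.0, 1.0]
    group_phase: global
  - name: ATP_ALPHA
    shift_start: -7.52
    linewidth_start: 12.0
    linewidth_lower: 2.0
    linewidth_upper: 60.0
    multiplet:
      n_components: 2
      j_hz: 16.0
      amplitude_ratios: [1.0, 1.0]
    group_phase: global
  - name: ATP_BETA
    shift_start: -16.26
    linewidth_start: 14.0
    linewidth_lower: 2.0
    linewidth_upper: 80.0
    multiplet:
      n_components: 3
      j_hz: 16.0
      amplitude_ratios: [1.0, 2.0, 1.0]
    group_phase: global
  - name: PDE
    shift_start: 2.9
    linewidth_start: 15.0
    linewidth_lower: 2.0
    linewidth_upper: 80.0
    group_phase: global
  - name: DPG_2
    shift_start: 5.25
    linewidth_start: 15.0
    linewidth_lower: 2.0
    linewidth_upper: 80.0
    group_phase: global
  - name: DPG_3
    shift_start: 6.51
    linewidth_start: 15.0
    linewidth_lower: 2.0
    linewidth_upper: 80.0
    group_phase: global
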
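# neurostim

A hardware-free reimplementation of the data-acquisition software stack for
a 512-channel neural micro-stimulation/recording system built from eight
64-channel bidirectional ASICs. The package is for electrophysiology and
ASIC-verification engineers who want to develop stimulation protocols,
exercise the full acquisition pipeline, and validate the channel-
characterization analyses without the chips, interface boards or digital-IO
cards: a behavioral simulator stands in for the silicon, and everything
around it — codec, demultiplexer, archiver, visualization DSP, test
analyses — is the production data path.

## The system in brief

The hardware exchanges two continuous 16-line, 50 MHz bitstreams with the
chips, handled in 0.5 s chunks (2.5×10⁷ 16-bit words; 95.37 MiB per second
of stream). The *output* stream carries register commands plus one
*real-time data command* per 25 µs sampling period and chip, setting each
channel's current-DAC codes. The instantaneous stimulation current obeys

```
Io = DAC10bit · DAC7bit · DAC4bit / ((2¹⁰−1)(2⁷−1)(2⁴−1)) · 15 µA,
```

negated when the polarity bit `p` is 0. In loopback testing the current
flows through the ~5.5 kΩ input resistor, so the expected recorded
amplitude at gain `g` is `V_ADC = g · Io · 5.5 kΩ`. Each channel's analogue
front end is a first-order active band-pass

```
K(s) = K₀ · s·T_H / ((1 + s·T_H)(1 + s·T_L)),
```

whose unit-step response `Y(t) = K₀·T_H/(T_L−T_H)·(e^(−t/T_L) − e^(−t/T_H))`
is what the filter-characterization procedure fits to extract the cut-offs
`f_hp = 1/(2π·T_H)` and `f_lp = 1/(2π·T_L)`. A 12-bit ADC maps ±1.8 V onto
codes 0–4095; the *input* stream multiplexes all 512 channel codes plus
eight trigger lines, and the demultiplexer recovers the canonical
520 × 20,000 per-chunk sample matrix (19.84 MiB).

Modules map onto the pipeline stages:

| module | role |
| --- | --- |
| `neurostim.protocol` | bit-packed command codec, chunk (de)serialization |
| `neurostim.stim` | pulse shapes, schedules, square waves, chunk builder, keep-alive queue |
| `neurostim.asic` | behavioral chip model: DAC law, band-pass + gain, ADC, multiplexer |
| `neurostim.demux` | demultiplexer, sync-queue filtering, code→volt conversion |
| `neurostim.characterize` | amplitude scans, gain/offset fits, Welch noise PSD, cut-off fits, spike fidelity |
| `neurostim.view` | min–max decimation, trigger-aligned averaging, Butterworth band splitting, spectra |
| `neurostim.archive` | HDF5 dataset writer/reader and the replay player |

## Worked example

Characterize one simulated channel the way the hardware test procedures do:
a 92 nA amplitude scan for the gain fit, then a 0.1 Hz square wave for the
filter cut-offs.

```python
import numpy as np
from neurostim import asic, characterize as ch

io = asic.io_current(48, 83, 3, 1)
print(f"stimulation current: {io*1e9:.1f} nA")
print(f"expected amplitude:  {asic.expected_amplitude(250, io)*1e3:.1f} mV")

vbar, currents, _ = ch.run_gain_scan(
    gain=250, repetitions=5,
    channel_params=asic.ChannelModelParams(white_rms=1e-4), seed=1)
gfit, ofit = ch.fit_gain_offset(vbar, currents)
print(f"fitted gain:   {gfit:.1f} V/V (programmed 250)")
print(f"fitted offset: {ofit*1e3:.2f} mV")

fit = ch.run_filter_characterization(fc_hp=0.6, fc_lp=1050.0,
                                     n_periods=10, noise_rms=1e-3, seed=1)
print(f"high-pass cut-off: {fit.fc_hp:.3f} Hz (programmed 0.600)")
print(f"low-pass cut-off:  {fit.fc_lp:.0f} Hz (programmed 1050)")
```

Output:

```
stimulation current: 92.0 nA
expected amplitude:  126.5 mV
fitted gain:   251.1 V/V (programmed 250)
fitted offset: 0.07 mV
high-pass cut-off: 0.600 Hz (programmed 0.600)
low-pass cut-off:  1049 Hz (programmed 1050)
```

The fitted gain sits within 0.5% of the programmed value (the small bias is
the high-pass droop across each 2.5 ms test pulse), and both cut-offs are
recovered to a fraction of a percent from only ten square-wave periods.
`run_gain_scan` exercises the whole stack: the schedule is compiled into
real output chunks, parsed by the simulated chip, filtered, digitized,
multiplexed onto the serial lines and demultiplexed back.

A `neurostim` command-line tool wraps the common operations:
`neurostim build --protocol exp.json --out chunks/`, `neurostim parse`,
`neurostim replay run.h5 --from 1.0 --to 2.0`, and
`neurostim characterize --dataset run.h5 --report out.json`.

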
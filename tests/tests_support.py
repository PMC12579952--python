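"""Shared constructors for hand-built spike events used across test modules."""

import numpy as np

from beetaste.spikes import SpikeEvent, _waveform_width_ms
from beetaste.synth import spike_template

FS = 30000.0


def event_at(time, amp=1.0, width_ms=0.8, fs=FS):
    """A SpikeEvent with a clean template waveform embedded at the centre."""
    tmpl = amp * spike_template(width_ms, fs)
    half = int(round(0.002 * fs))
    h = len(tmpl) // 2
    if h > half:
        tmpl = tmpl[h - half : h + half + 1]
        h = half
    wf = np.zeros(2 * half + 1)
    wf[half - h : half + h + 1] = tmpl
    return SpikeEvent(
        time=time, peak_amplitude=amp, waveform=wf,
        width_ms=_waveform_width_ms(wf, fs),
    )


def constructed_amplitude_events():
    """99 events of amplitude 1.0 plus one of amplitude 10.0; the sample
    mean is 1.09 and sample SD exactly 0.9, so mean + 3 SD = 3.79."""
    events = [event_at(0.2 + i * 0.01, 1.0) for i in range(99)]
    events.append(event_at(0.2 + 99 * 0.01, 10.0))
    return events
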
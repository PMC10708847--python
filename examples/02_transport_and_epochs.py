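"""Packetize a trace, lose a packet, and watch epoch assembly recover.

The acquisition layer mimics the platform's client-server transport: one
server instance admits at most four headsets, samples travel in
fixed-size packets, and the processor cuts contiguous 2-s epochs (1024
samples).  A sequence gap invalidates the partially filled window.
"""

from betawatch.acquisition import accept_clients, assemble_epochs, packetize
from betawatch.synthetic import SignalSpec, generate_trace

adm = accept_clients(requested=5)
print(f"connection attempts: 5, accepted: {adm.n_accepted}, refused: {len(adm.refused)}")

trace = generate_trace(SignalSpec(duration_s=8.0, seed=7))
packets = packetize(trace, packet_size=512)   # one second per packet
print(f"trace: {len(trace)} samples -> {len(packets)} packets of 512")

epochs, log = assemble_epochs(packets)
print(f"gap-free: {log.n_epochs} epochs of 1024, {log.n_discarded_windows} discarded")

lossy = [p for p in packets if p.seq != 3]     # drop the 4th second
epochs, log = assemble_epochs(lossy)
print(f"with a gap: epochs {[e.index for e in epochs]}, "
      f"{log.n_discarded_windows} window discarded at the gap")
# Epoch 1 was half filled when packet 3 went missing, so it is dropped
# rather than zero-filled (zero-filling would bias the PSD downward).
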
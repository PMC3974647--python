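well,cell_line,reporter,perturbation,is_control
A01,MMH-D3,Per2-dLuc,NS,True
A02,MMH-D3,Per2-dLuc,NS,True
A03,MMH-D3,Per2-dLuc,NS,True
A04,MMH-D3,Per2-dLuc,Per3,False
A05,MMH-D3,Per2-dLuc,Per3,False
A06,MMH-D3,Per2-dLuc,Per3,False
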
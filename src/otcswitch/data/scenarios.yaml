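# Built-in switch scenarios (rates s1..s6 for Pop 1..Pop 6).
scenarios:
  - name: base
    switch_rates: [20%, 20%, 3%, 3%, 0%, 0%]
  - name: A          # Rx-treated patients do not switch
    switch_rates: [0%, 0%, 3%, 3%, 0%, 0%]
  - name: B          # undiagnosed patients also switch
    switch_rates: [20%, 20%, 3%, 3%, 3%, 3%]
  - name: C          # weaker adverse-event risk mitigation
    switch_rates: [20%, 20%, 3%, 3%, 0%, 0%]
    ae_mitigation_override: 90%
  - name: D          # OTC product loses its reimbursable Rx status
    switch_rates: [20%, 20%, 3%, 3%, 0%, 0%]
    disreimbursement: true
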
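nominal_gmo_percent: 0.1
conversion_factor: 1.0
genes:
  transgene:
    standards:
    - position: A1
      copies: 100000.0
    - position: A2
      copies: 100000.0
    - position: A3
      copies: 100000.0
    - position: A4
      copies: 10000.0
    - position: A5
      copies: 10000.0
    - position: A6
      copies: 10000.0
    - position: A7
      copies: 1000.0
    - position: A8
      copies: 1000.0
    - position: A9
      copies: 1000.0
    - position: A10
      copies: 100.0
    - position: A11
      copies: 100.0
    - position: A12
      copies: 100.0
    - position: B1
      copies: 10.0
    - position: B2
      copies: 10.0
    - position: B3
      copies: 10.0
    ntc:
    - B4
    samples:
      isolation1:
      - B5
      - B6
      - B7
      - B8
      - B9
      - B10
      - B11
      - B12
      - C1
      - C2
      - C3
      - C4
      - C5
      - C6
      - C7
      - C8
      isolation2:
      - C9
      - C10
      - C11
      - C12
      - D1
      - D2
      - D3
      - D4
      - D5
      - D6
      - D7
      - D8
      - D9
      - D10
      - D11
      - D12
  reference:
    standards:
    - position: E1
      copies: 100000.0
    - position: E2
      copies: 100000.0
    - position: E3
      copies: 100000.0
    - position: E4
      copies: 10000.0
    - position: E5
      copies: 10000.0
    - position: E6
      copies: 10000.0
    - position: E7
      copies: 1000.0
    - position: E8
      copies: 1000.0
    - position: E9
      copies: 1000.0
    - position: E10
      copies: 100.0
    - position: E11
      copies: 100.0
    - position: E12
      copies: 100.0
    - position: F1
      copies: 10.0
    - position: F2
      copies: 10.0
    - position: F3
      copies: 10.0
    ntc:
    - F4
    samples:
      isolation1:
      - F5
      - F6
      - F7
      - F8
      - F9
      - F10
      - F11
      - F12
      - G1
      - G2
      - G3
      - G4
      - G5
      - G6
      - G7
      - G8
      isolation2:
      - G9
      - G10
      - G11
      - G12
      - H1
      - H2
      - H3
      - H4
      - H5
      - H6
      - H7
      - H8
      - H9
      - H10
      - H11
      - H12
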
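rCRS
  L1b: C6548T, T6827C, A6989G, A7055G, T7389C, C7915T, A8248G, T12519C, A14203G, T16126C, C16264T, C16270T
    L1b1a: G5460A, T10688C, A13789G
      L1b1a3: A8527G, T9072C
        L1b1a3a: G12693A, T14178C, C16293T
  L2: A7146G, A9221G, C13506T, G8206A, T10115C, C16311T
    L2a: C8468T, C8655T, T10810C, G11914A, T11944C, A13590G, A13803G, G15301A
      L2a1: C16294T, T12195C
    L2c: G13958c, T15849C, C16187T, A2332G, T3918C
  L3: A769G, A1018G, C16223T, G3849A, T5442C
    L3d: C7424T, G1719A, T8618C, A15824G
      L3d1: T16124C, A14284G, C5773T, G9932A
    L3e: G2352A, T14212C, C9377T
      L3e2: T2483C, G14905A, A10086G
        L3e2b: A16265c, T6221C, G5147A
          L3e2b1a: T10873C, A15924G, C1048T, G4104A
      L3e3: T3398C, G15431A, A8787G
        L3e3b: G6261A, A10819G, T4823C
    M: T489C, C10400T, T14783C, G15043A
      C1: A493G, T9545C, G12672A, 16325d
    N: G8701A, A9540G, C14766T, G11016A
      R: T12705C, A11719G, C12557T
        HV: !C14766T, C14872T, A5656G
          HV0a: T72C, A15904G, G5252A
            V1a: G4580A, T16298C, A3672G
          H: A2706G, C7028T, G5471A
            H1: G3010A, T6776C
              H1c: T477C, A9150G
                H1c3: C6366T, G8865A
        JT: T4216C, G11251A
          J: C295T, G13708A, A12612G
            J1c5: C462T, T14798C, G8269A
            J2a1a1: A7789G, C16231T, G15257A, T10172C
        U: A11467G, G12308A, A12372G
          U4b: T4646C, T16356C, A6047G
          U5a: C16256T, A14793G, T3197C
          K: G9055A, T1189C, C14167T
            K1a4a1: T11025C, A10978G, C2789T
              K1a4a1a: G9962A, T16093C, A8149G
        F1c: G6962A, T16304C, C3970T, A5263G, T6392C
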
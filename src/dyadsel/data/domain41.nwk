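(((((T2:0.186527,(T25:0.213232,T28:0.434645):0.173452):0.551943,(T38:0.384015,(T20:0.107211,(T3:0.00704125,(T21:0.10334,T31:0.138073):0.833157):0.00908962):0.00695763):0.22066):0.112295,((T23:0.058492,((T14:0.490326,T29:0.19505):0.0336147,(T41:0.139827,(T5:0.164303,T13:0.340052):0.174745):0.145906):0.254517):0.215799,(T9:0.234791,T12:0.421426):1.48445):0.62825):0.209159,((T32:0.389491,(T33:0.0459362,(T17:0.093244,(T26:0.609393,T34:0.123255):0.044556):0.0444303):0.163915):0.046935,(T8:0.187988,(T4:0.0490983,T18:0.114969):0.0661252):0.0817223):0.02316):0.668406,((T7:0.330343,(T22:0.588142,(T19:0.207778,((T6:0.124736,T37:0.0208507):0.111015,(T11:0.161145,T35:0.298218):0.0758128):0.118156):0.0689395):0.00692444):0.163581,(((T10:0.293802,T36:0.276913):0.247467,((T27:0.894007,(T24:0.108086,T40:0.0310532):0.0792069):0.0350253,(T16:0.132101,T30:0.0963131):0.691518):0.17192):0.123354,(T39:0.23845,(T1:0.353622,T15:0.517833):0.460392):0.0199636):0.016572):0.258818);
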
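roi,network
roi1,VIS
roi2,VIS
roi3,VIS
roi4,VIS
roi5,VIS
roi6,VIS
roi7,VIS
roi8,VIS
roi9,VIS
roi10,SMN
roi11,SMN
roi12,SMN
roi13,SMN
roi14,SMN
roi15,SMN
roi16,DAN
roi17,DAN
roi18,DAN
roi19,DAN
roi20,DAN
roi21,DAN
roi22,DAN
roi23,DAN
roi24,VAN
roi25,VAN
roi26,VAN
roi27,VAN
roi28,VAN
roi29,VAN
roi30,VAN
roi31,LIM
roi32,LIM
roi33,LIM
roi34,FPC
roi35,FPC
roi36,FPC
roi37,FPC
roi38,DMN
roi39,DMN
roi40,DMN
roi41,DMN
roi42,DMN
roi43,DMN
roi44,DMN
roi45,DMN
roi46,DMN
roi47,DMN
roi48,DMN
roi49,DMN
roi50,DMN
roi51,VIS
roi52,VIS
roi53,VIS
roi54,VIS
roi55,VIS
roi56,VIS
roi57,VIS
roi58,VIS
roi59,VIS
roi60,SMN
roi61,SMN
roi62,SMN
roi63,SMN
roi64,SMN
roi65,SMN
roi66,DAN
roi67,DAN
roi68,DAN
roi69,DAN
roi70,DAN
roi71,DAN
roi72,DAN
roi73,DAN
roi74,VAN
roi75,VAN
roi76,VAN
roi77,VAN
roi78,VAN
roi79,VAN
roi80,VAN
roi81,LIM
roi82,LIM
roi83,LIM
roi84,FPC
roi85,FPC
roi86,FPC
roi87,FPC
roi88,DMN
roi89,DMN
roi90,DMN
roi91,DMN
roi92,DMN
roi93,DMN
roi94,DMN
roi95,DMN
roi96,DMN
roi97,DMN
roi98,DMN
roi99,DMN
roi100,DMN
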
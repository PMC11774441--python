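sample,batch,f0,f1,f2,f3,f4,f5
s00,b1,4.31380356252,-4.52619949995,2.07885683364,-0.472237101637,-0.63331526937,-1.57931680609
s01,b1,-2.8852995264,-4.86125125166,2.21069796904,-1.62110696042,-2.40531793375,0.457050753226
s02,b1,2.05965836922,-6.76122621672,3.32549125395,-1.29757544689,-2.73970748858,2.34079471944
s03,b1,2.22353165616,-3.81850606075,2.59232901396,-0.416015338222,-0.669260091847,4.3630057272
s04,b1,2.7025481332,-3.8812831343,3.24018615945,-1.08063949457,-2.4039561126,2.94870062739
s05,b1,1.15550555558,-3.54368182809,2.6759026856,-0.545624932554,-1.43890953851,0.162046607029
s06,b1,-0.93444377148,-7.19024381239,2.52470463602,-2.14465844285,-0.825641524472,5.60782596762
s07,b1,0.420574616935,-2.35464374694,3.92541304039,-0.46226965122,-1.66209430171,1.79031906575
s08,b1,-0.618525682146,-2.74024385611,3.1987105503,-1.99977947196,-1.44059933051,4.62497527688
s09,b1,2.07994034017,-4.14692691577,3.2763134773,-1.58187435983,-0.695619724175,3.78584985616
s10,b1,4.85844196492,-6.12266477712,3.48683369688,-3.18702117845,-2.40071404836,-1.44505688044
s11,b1,1.96756948545,-2.78098684848,5.10817751006,-0.398554995133,-1.80476622794,2.07837511114
s12,b1,5.19635855898,-5.59477926843,4.63990388403,0.898578107714,-2.56727443527,2.60295605416
s13,b1,2.06644003047,-8.71656631305,2.04645985685,-3.29037254851,-1.46136571595,2.82490589809
s14,b1,2.82605096355,-4.29251856442,4.17859544257,-1.1487137918,-2.17618690912,-1.75272082726
s15,b1,2.77725911747,-1.02022177515,3.03287187915,-1.578470857,-0.738750021599,3.00324291299
s16,b1,1.0513541249,-5.89637165462,2.08601976797,-1.11564581001,-1.20470633483,1.02095653194
s17,b1,1.47542763097,-4.32099789955,1.77725539922,0.410944752698,-0.098493632257,3.57691631564
s18,b1,-0.778384755967,-1.11276026045,2.60097857993,-1.75662504595,0.0688509817123,2.08660082532
s19,b1,1.74092186359,-2.73348423473,4.569928022,-3.10512112733,-1.17285442697,1.26653950673
s20,b1,5.95534492649,-7.04916681327,4.02732320545,-1.61144684693,0.750816582304,4.0673265038
s21,b1,3.10363237209,0.280576337916,2.84012637014,-0.809889518621,0.0456158532078,4.15287766647
s22,b1,1.87405683305,-3.23793243236,3.1049542033,-3.16472383991,-1.41904231658,0.322102666257
s23,b1,1.5255113243,-1.52514549317,2.02431113825,-0.53849504753,-1.78766407892,5.25768135998
s24,b1,3.34371603513,-3.37463034684,5.37033393507,-1.49556250573,-2.94681869516,3.05898604288
s25,b2,0.60123110371,-5.1206032491,1.05163371594,1.26470682538,-4.53422189667,2.04233521128
s26,b2,1.52066099447,-8.41345339075,1.58063243727,-3.29055435413,-0.793708711906,4.12933337341
s27,b2,0.549398607928,-3.23225861466,1.65947923345,-2.48178717779,-2.50862896365,-0.301579722921
s28,b2,1.73586869188,-7.9979388761,2.04674944999,0.870045320201,-1.85063244387,5.969651068
s29,b2,4.79208842363,-9.02658926388,1.8583927049,0.2014694333,-3.27873067563,-2.03028575451
s30,b2,3.38423036237,-4.75741823813,2.20850200522,0.0655105882267,0.18530861532,3.18909524088
s31,b2,1.83378894414,-6.99180004496,2.45925285956,-0.779090417126,-1.62667552211,-1.58745281765
s32,b2,1.38498811214,-9.15763905281,1.07363709234,1.68814527173,-1.97713048916,7.03221754057
s33,b2,1.17998036995,-9.46662487813,0.88478589679,-3.57095850326,-0.231204052761,0.964580666992
s34,b2,-0.976630880706,-3.09738819276,1.78397637516,3.08052370855,-0.214900599849,1.70676283404
s35,b2,0.804284894721,-9.52081887342,1.47663253976,2.96233376994,-1.85412696641,-2.30772554206
s36,b2,1.73697623741,-1.88971440426,1.0170377927,-2.41620598465,0.11230105223,2.75048624477
s37,b2,2.12459869027,-4.63193992316,2.93057869268,1.17051979394,-1.06750159271,4.79132371459
s38,b2,3.75805935142,-7.61152248806,1.29136501871,2.48371672087,-2.7248405549,6.74680242556
s39,b2,-1.53591342898,-9.55866706109,2.5674390606,-1.81482098397,0.582893470224,3.39495061681
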
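-5.9272082325855036e-01 +7.5060200586513665e-02 -8.0190273223354125e-01
-4.4165827236693728e-01 +1.1241127723845099e-01 +8.9011329346295698e-01
+2.8641837486718497e-01 +7.7108924763921438e-01 +5.6867027943583526e-01
-3.0771616822323922e-01 +4.8257936644621535e-01 -8.2001702110040153e-01
+5.0511724757043602e-02 +1.1578997915084853e-01 -9.9198853138043619e-01
+4.3167253492923863e-01 -8.8143191824425882e-01 +1.9166793181962274e-01
+9.5811274597109009e-01 -2.1834844793766902e-02 -2.8555770968504696e-01
-6.5510017279350108e-01 -2.2571898231777279e-01 +7.2103724219165954e-01
-2.3919282889796609e-01 -1.8536141016908234e-01 -9.5311486098156994e-01
+9.2544243732756704e-01 +3.7738921189816060e-01 -3.3670134185913962e-02
+8.0442034164278065e-01 -5.8175274908919483e-01 +1.2029818318859395e-01
+9.7522866340226477e-01 -1.3327331579094037e-01 +1.7654256533969490e-01
+3.7301970018846178e-02 +5.5688813466326059e-01 +8.2974946128574700e-01
-8.4973458727091677e-01 -3.7034526567422188e-01 -3.7522728497300761e-01
-6.3569584839871573e-01 -4.0708857105663881e-01 -6.5587322223406919e-01
-6.9094957479600483e-01 +6.7112298276074323e-01 +2.6866824728565031e-01
+7.1105347676185904e-01 +5.1104981474753663e-01 -4.8293999630531820e-01
-4.8120601825593262e-01 -8.4968067684800008e-01 -2.1560036035544008e-01
+8.2992096854707098e-02 +9.6300532361644464e-01 -2.5638459108543493e-01
+2.9615821993801222e-01 -8.5007626399376579e-01 -4.3550046401530873e-01
-6.1487474785352614e-01 -7.7887631949096092e-01 +1.2361522312513618e-01
+8.1644991614797313e-01 -2.9294216762310527e-01 -4.9758860602936256e-01
+8.0668262210296937e-01 -2.7506444991329831e-01 +5.2307044993095564e-01
+2.3029859974789502e-01 +7.9627103020223411e-01 -5.5938805977141803e-01
-4.0854166469706155e-01 +5.0995175685532557e-01 +7.5699598009944580e-01
-4.1189772724059226e-01 +7.2222137351751725e-01 -5.5564066619399399e-01
-1.9454637379064668e-01 -5.1252091041304915e-01 +8.3634563718255228e-01
+5.3057809472896351e-02 -9.8479335162072590e-01 -1.6542951205137219e-01
+5.9272082325855036e-01 -7.5060200586513665e-02 +8.0190273223354125e-01
+4.4165827236693728e-01 -1.1241127723845099e-01 -8.9011329346295698e-01
-2.8641837486718497e-01 -7.7108924763921438e-01 -5.6867027943583526e-01
+3.0771616822323922e-01 -4.8257936644621535e-01 +8.2001702110040153e-01
-5.0511724757043602e-02 -1.1578997915084853e-01 +9.9198853138043619e-01
-4.3167253492923863e-01 +8.8143191824425882e-01 -1.9166793181962274e-01
-9.5811274597109009e-01 +2.1834844793766902e-02 +2.8555770968504696e-01
+6.5510017279350108e-01 +2.2571898231777279e-01 -7.2103724219165954e-01
+2.3919282889796609e-01 +1.8536141016908234e-01 +9.5311486098156994e-01
-9.2544243732756704e-01 -3.7738921189816060e-01 +3.3670134185913962e-02
-8.0442034164278065e-01 +5.8175274908919483e-01 -1.2029818318859395e-01
-9.7522866340226477e-01 +1.3327331579094037e-01 -1.7654256533969490e-01
-3.7301970018846178e-02 -5.5688813466326059e-01 -8.2974946128574700e-01
+8.4973458727091677e-01 +3.7034526567422188e-01 +3.7522728497300761e-01
+6.3569584839871573e-01 +4.0708857105663881e-01 +6.5587322223406919e-01
+6.9094957479600483e-01 -6.7112298276074323e-01 -2.6866824728565031e-01
-7.1105347676185904e-01 -5.1104981474753663e-01 +4.8293999630531820e-01
+4.8120601825593262e-01 +8.4968067684800008e-01 +2.1560036035544008e-01
-8.2992096854707098e-02 -9.6300532361644464e-01 +2.5638459108543493e-01
-2.9615821993801222e-01 +8.5007626399376579e-01 +4.3550046401530873e-01
+6.1487474785352614e-01 +7.7887631949096092e-01 -1.2361522312513618e-01
-8.1644991614797313e-01 +2.9294216762310527e-01 +4.9758860602936256e-01
-8.0668262210296937e-01 +2.7506444991329831e-01 -5.2307044993095564e-01
-2.3029859974789502e-01 -7.9627103020223411e-01 +5.5938805977141803e-01
+4.0854166469706155e-01 -5.0995175685532557e-01 -7.5699598009944580e-01
+4.1189772724059226e-01 -7.2222137351751725e-01 +5.5564066619399399e-01
+1.9454637379064668e-01 +5.1252091041304915e-01 -8.3634563718255228e-01
-5.3057809472896351e-02 +9.8479335162072590e-01 +1.6542951205137219e-01
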